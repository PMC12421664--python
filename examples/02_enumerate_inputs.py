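"""Enumerate every calculation a complete LED study needs.

Uses a DNA-duplex-like layout — two subsystems ("strands") of three
fragments ("nucleobases") each — and reproduces the campaign arithmetic:
18 inputs per setting without counterpoise correction, 30 with, growing to
72/120 over the four settings a combined CBS+CPS extrapolation requires.
"""

from ledkit import Setting, enumerate_campaign, enumerate_nbody, enumerate_twobody, generate_ground_truth, render_input

# stand-in geometry with the right fragment structure (2 subsystems x 3)
gt = generate_ground_truth(2, (3, 3), seed=0)
geom, subsystems = gt.geometry, gt.subsystems
tz = Setting("tz", "def2-TZVP")

nbody = enumerate_nbody(geom, subsystems, tz, bsse=True)
print(f"N-body inputs: {len(nbody)} (supersystem + one per subsystem)")

for bsse in (False, True):
    tb = enumerate_twobody(geom, subsystems, tz, bsse=bsse)
    pairs = sum(s.role == "pair" for s in tb)
    monos = sum(s.role == "monomer" for s in tb)
    print(f"two-body ({'corrected' if bsse else 'uncorrected'}): {pairs} pairs + {monos} monomers")

for bsse in (False, True):
    per_setting = enumerate_campaign(geom, subsystems, [tz], bsse, include_twobody=True)
    four = enumerate_campaign(geom, subsystems, [Setting(f"s{i}", "b") for i in range(4)], bsse, True)
    print(f"{'corrected' if bsse else 'uncorrected'}: {len(per_setting)} per setting, {len(four)} for CBS+CPS")

# what one counterpoise monomer input looks like: fragment 1 real, its
# partner's atoms present as ghosts (element followed by a colon)
mono = next(s for s in enumerate_twobody(geom, subsystems, tz, bsse=True) if s.role == "monomer")
print("\n--- rendered input:", mono.filename, "---")
print(render_input(mono, geom))
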