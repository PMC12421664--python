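# LED output grammar

`ledkit` parses a documented plain-text grammar modelled on the LED blocks a
DLPNO-CCSD(T)/HFLD engine prints. The mock writer
(`ledkit.ledout.write_led_output`) emits exactly this grammar; the parser is
whitespace-tolerant, reads numbers at full printed precision, and ignores
unrecognized trailing content, so real outputs that conform also parse.

## Annotated example

```
==================== LED ANALYSIS ====================
Method  : DLPNO-CCSD(T)            # method tag; "HFLD" enables term exclusion
Setting : tz                       # free-form setting label

FRAGMENT TABLE                     # fragment labels, ghost flags, coordinates
FRAGMENT 1 (real)
  O      0.005478    -0.009209    -0.018361
  H      0.740661     0.602531     0.016510
  H     -0.755735     0.599180     0.001745
FRAGMENT 2 (ghost)                 # ghost fragments: basis functions only;
  O     12.619233     0.007422     0.006018   # carry no intra or pair terms
  H     13.367538     0.585557    -0.014596
  H     11.848860     0.591014    -0.007590
END OF FRAGMENT TABLE

FINAL SINGLE POINT ENERGY      -76.298765432101   # required; Hartree
REFERENCE ENERGY               -76.010000000000   # optional

INTRA FRAGMENT 1                   # one block per real fragment
  Intra REF. energy            -76.001234567890
  Intra correlation energy      -0.297530864211   # may be absent (crashed run)

INTERACTION OF FRAGMENTS 1 AND 2   # one block per real fragment pair
  Electrostatics (REF.)         -0.010000000000
  Exchange (REF.)               -0.002000000000
  Non-dispersion (CORR.)        -0.001000000000
  Dispersion (CORR.)            -0.003000000000
  Solvation                     -0.000500000000   # optional (implicit solvent)
  Total interaction             -0.016500000000   # validated against the sum
```

## Rules

* Coordinates are in Å, energies in Hartree.
* Fragment labels inside a file are local (contiguous from 1, real fragments
  first); `ledkit.ledout.align_labels` maps them onto supersystem labels by
  element-sequence and coordinate matching (default tolerance 1e-4 Å).
* A missing `FINAL SINGLE POINT ENERGY` line is a parse error naming the
  block; a malformed line inside a pair block is a parse error carrying the
  line number; a stored pair total deviating from the component sum by more
  than 1e-9 Eh is a parse error.
* Any component or intra line may be absent; the corresponding record field
  is `None` and can be filled from an alternative output with
  `merge_alternative` (fields present in the main record always win).
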