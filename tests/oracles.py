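"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: fragmentation is
checked against a hand-rolled union-find, calculation counts against
explicit set enumeration, and the extrapolation formulas against a direct
linear-system solve.
"""

import itertools

import numpy as np

from ledkit import Atom, Geometry, covalent_radius


def union_find_partition(n: int, edges) -> list[frozenset]:
    """Connected components via union-find over an explicit edge list."""
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, set] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]


def brute_force_edges(geom: Geometry, cutoff_scale: float = 1.15):
    """Direct O(n^2) distance/threshold arithmetic, no graph library."""
    edges = []
    for i, j in itertools.combinations(range(len(geom.atoms)), 2):
        d = float(np.linalg.norm(geom.atoms[i].position - geom.atoms[j].position))
        r = covalent_radius(geom.atoms[i].element) + covalent_radius(geom.atoms[j].element)
        if d <= cutoff_scale * r:
            edges.append((i, j))
    return edges


def random_geometry(rng: np.random.Generator, n_atoms: int, box: float = 6.0) -> Geometry:
    elements = rng.choice(["H", "C", "N", "O"], size=n_atoms)
    coords = rng.uniform(0.0, box, size=(n_atoms, 3))
    return Geometry(atoms=[Atom(el, xyz) for el, xyz in zip(elements, coords)])


def brute_force_counts(f: list[int], bsse: bool, include_twobody: bool) -> int:
    """Per-setting calculation count by explicit enumeration of roles."""
    S = len(f)
    F = sum(f)
    # assign fragments to subsystems consecutively
    sub_of = {}
    fid = 1
    for k, fi in enumerate(f):
        for _ in range(fi):
            sub_of[fid] = k
            fid += 1
    pairs = [
        (x, y)
        for x, y in itertools.combinations(range(1, F + 1), 2)
        if sub_of[x] != sub_of[y]
    ]
    count = 1 + S  # supersystem + subsystems
    if include_twobody:
        count += len(pairs)
        count += 2 * len(pairs) if bsse else F
    return count


def solve_cbs_reference(e_x, e_y, x, y, alpha):
    """Fit E(n) = E_inf + A exp(-alpha sqrt(n)) through two points by linear solve."""
    m = np.array([[1.0, np.exp(-alpha * np.sqrt(x))], [1.0, np.exp(-alpha * np.sqrt(y))]])
    e_inf, _ = np.linalg.solve(m, np.array([e_x, e_y]))
    return float(e_inf)


def solve_cbs_correlation(e_x, e_y, x, y, beta):
    """Fit E(n) = E_inf + B n^-beta through two points by linear solve."""
    m = np.array([[1.0, x ** (-beta)], [1.0, y ** (-beta)]])
    e_inf, _ = np.linalg.solve(m, np.array([e_x, e_y]))
    return float(e_inf)
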