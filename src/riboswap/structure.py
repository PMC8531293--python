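"""Solvent-accessible surface area (SASA) of chains within a complex.

Exchanging ribosomal proteins sit on the ribosome surface; stable ones are
buried among rRNA and neighbouring proteins.  The quantity compared is a
chain's *accessible fraction*: its SASA computed inside the full complex
divided by its SASA computed in isolation.

SASA uses the Shrake-Rupley method with a deterministic golden-spiral
point set: each atom's solvent sphere (van der Waals radius + probe
radius) is sampled with ``n_points`` quasi-uniform points and the exposed
fraction of points, times the sphere area, is the atom's contribution.
Results are reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu

__all__ = [
    "VDW_RADII",
    "Structure",
    "golden_spiral_points",
    "sasa",
    "ChainSASA",
    "chain_accessible_fraction",
    "all_chain_fractions",
    "compare_accessibility",
]

#: van der Waals radii in Angstrom (Bondi-style defaults, overridable)
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "MG": 1.73, "ZN": 1.39, "FE": 1.40, "K": 2.75, "NA": 2.27,
}
DEFAULT_RADIUS = 1.70


@dataclass
class Structure:
    """Minimal coordinate container: positions, radii and chain ids."""

    coords: np.ndarray  # (n, 3) Angstrom
    radii: np.ndarray  # (n,)
    chain_ids: np.ndarray  # (n,) str

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float)
        self.chain_ids = np.asarray(self.chain_ids)
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if (self.radii <= 0).any():
            raise ValueError("radii must be positive")
        if len(self.radii) != len(self.coords) != len(self.chain_ids):
            raise ValueError("coords, radii and chain_ids must align")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def chains(self) -> list[str]:
        return sorted(set(self.chain_ids.tolist()))

    def select_chain(self, chain: str) -> "Structure":
        mask = self.chain_ids == chain
        if not mask.any():
            raise KeyError(f"chain {chain!r} not present")
        return Structure(self.coords[mask], self.radii[mask],
                         self.chain_ids[mask])

    @classmethod
    def from_pdb(cls, path, model: int = 1,
                 radii: dict[str, float] | None = None) -> "Structure":
        """Load the first model of a PDB file (hydrogens and waters kept
        if present; radii assigned per element)."""
        from biotite.structure.io.pdb import PDBFile
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=model)
        table = dict(VDW_RADII)
        if radii:
            table.update({k.upper(): v for k, v in radii.items()})
        r = np.array([table.get(el.upper(), DEFAULT_RADIUS)
                      for el in atoms.element])
        return cls(atoms.coord, r, atoms.chain_id.astype(str))


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci
    lattice): z descends linearly, azimuth advances by the golden angle."""
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def sasa(structure: Structure, probe: float = 1.4,
         n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake-Rupley).

    An atom's accessible area is (exposed points / n_points) * 4 pi
    (r + probe)^2, a point being exposed when it lies outside every other
    atom's solvent sphere.  Returns an array aligned with the atoms; sum
    for the total.
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    coords, radii = structure.coords, structure.radii
    n = len(coords)
    sphere = golden_spiral_points(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach)
                     if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > expanded[j] ** 2
        areas[i] = exposed.mean() * 4.0 * math.pi * expanded[i] ** 2
    return areas


@dataclass
class ChainSASA:
    """A chain's surface areas inside and outside its complex."""

    chain: str
    sasa_in_complex: float
    sasa_isolated: float

    @property
    def accessible_fraction(self) -> float:
        return self.sasa_in_complex / self.sasa_isolated


def chain_accessible_fraction(structure: Structure, chain: str,
                              probe: float = 1.4,
                              n_points: int = 960) -> ChainSASA:
    """Accessible fraction of one chain: SASA of its atoms with all other
    chains present, over SASA of the chain isolated."""
    mask = structure.chain_ids == chain
    if not mask.any():
        raise KeyError(f"chain {chain!r} not present")
    in_complex = float(sasa(structure, probe, n_points)[mask].sum())
    isolated = float(sasa(structure.select_chain(chain), probe,
                          n_points).sum())
    if isolated <= 0:
        raise ValueError(f"chain {chain!r} has zero isolated SASA")
    return ChainSASA(chain=chain, sasa_in_complex=in_complex,
                     sasa_isolated=isolated)


def all_chain_fractions(structure: Structure, probe: float = 1.4,
                        n_points: int = 960) -> list[ChainSASA]:
    """Accessible fraction for every chain, sharing one in-complex pass."""
    per_atom = sasa(structure, probe, n_points)
    out = []
    for chain in structure.chains:
        mask = structure.chain_ids == chain
        isolated = float(sasa(structure.select_chain(chain), probe,
                              n_points).sum())
        if isolated <= 0:
            raise ValueError(f"chain {chain!r} has zero isolated SASA")
        out.append(ChainSASA(chain=chain,
                             sasa_in_complex=float(per_atom[mask].sum()),
                             sasa_isolated=isolated))
    return out


def compare_accessibility(values, groups) -> dict:
    """Mann-Whitney comparison of accessible fractions between the stable
    and exchanger groups (two-tailed; exact for small tie-free samples,
    normal approximation with tie correction otherwise)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValueError("need exactly two non-empty groups")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError("a group is empty")
    res = mannwhitneyu(a, b, alternative="two-sided")
    u_small = min(float(res.statistic), a.size * b.size - float(res.statistic))
    return {
        "U": u_small,
        "p_value": float(res.pvalue),
        "medians": {labels[0]: float(np.median(a)),
                    labels[1]: float(np.median(b))},
        "n": {labels[0]: int(a.size), labels[1]: int(b.size)},
    }
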