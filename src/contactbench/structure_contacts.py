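"""CA-trace geometry: coordinates, distance matrices, contact maps.

A "contact" is defined purely on the CA–CA distance: residues i and j are
in contact at cutoff c when d(CA_i, CA_j) <= c. Contact maps are built
over a ladder of cutoffs from 3.8 to 20 Å; the pair universe is all
n(n-1)/2 unordered pairs with no minimum sequence separation, so confusion
counts over the universe always sum to n(n-1)/2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

log = logging.getLogger(__name__)

#: distance cutoffs (Å) at which contact maps are evaluated
CUTOFF_LADDER: tuple[float, ...] = (
    3.8, 4.0, 4.5, 5.0, 5.5, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0
)


@dataclass(frozen=True)
class CoordinateSet:
    """One CA position per residue, in file order.

    ``residue_numbers`` keeps the author numbering from the coordinate
    file for reporting; all pair indices downstream are sequential
    1..n positions.
    """

    coords: np.ndarray  # (n, 3) float, Å
    residue_numbers: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if len(self.residue_numbers) != len(self.coords):
            raise ValueError("residue_numbers length mismatch")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric CA–CA Euclidean distance matrix (Å)."""

    d: np.ndarray

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass(frozen=True)
class ContactMap:
    """Unordered residue pairs (1-based, i<j) within ``cutoff`` Å."""

    cutoff: float
    contacts: frozenset[tuple[int, int]]
    n_residues: int

    @property
    def universe_size(self) -> int:
        return self.n_residues * (self.n_residues - 1) // 2


def read_ca_coordinates(path, chain: str = "A") -> CoordinateSet:
    """Extract one CA per residue from a PDB file.

    Alternate locations resolve to the highest-occupancy conformer (ties:
    first in file, Biopython's rule). Residues without a CA atom are
    skipped with a warning. Raises ``ValueError`` when the chain is absent
    (naming the chains present) or contains no CA atoms.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    chains = {c.id: c for c in model.get_chains()}
    if chain not in chains:
        raise ValueError(
            f"chain {chain!r} not found in {path}; available: "
            f"{sorted(chains)}"
        )
    coords, numbers = [], []
    for res in chains[chain].get_residues():
        hetflag, resseq, _icode = res.id
        if hetflag.strip():
            continue
        if "CA" not in res:
            log.warning("residue %s %s lacks a CA atom; skipped", res.resname, resseq)
            continue
        atom = res["CA"]
        if atom.is_disordered():
            atom = max(atom, key=lambda a: a.get_occupancy() or 0.0)
        coords.append(atom.get_coord())
        numbers.append(resseq)
    if not coords:
        raise ValueError(f"chain {chain!r} in {path} has no CA atoms")
    return CoordinateSet(np.asarray(coords, dtype=float), tuple(numbers))


def distance_matrix(coords: CoordinateSet) -> DistanceMatrix:
    """All-pairs Euclidean CA–CA distances."""
    if len(coords) < 2:
        raise ValueError("need >=2 residues")
    return DistanceMatrix(squareform(pdist(coords.coords)))


def contact_map(dm: DistanceMatrix, cutoff: float) -> ContactMap:
    """All unordered pairs i<j with d(i, j) <= cutoff (closed boundary)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    iu, ju = np.triu_indices(dm.n, k=1)
    mask = dm.d[iu, ju] <= cutoff
    pairs = frozenset(
        (int(i) + 1, int(j) + 1) for i, j in zip(iu[mask], ju[mask])
    )
    return ContactMap(cutoff, pairs, dm.n)


def contact_map_ladder(
    dm: DistanceMatrix, ladder: tuple[float, ...] = CUTOFF_LADDER
) -> list[ContactMap]:
    """Contact maps at every ladder cutoff (nested by construction)."""
    return [contact_map(dm, c) for c in ladder]


def write_contact_table(dm: DistanceMatrix, path, ladder=CUTOFF_LADDER) -> None:
    """TSV of i, j, distance and one boolean column per ladder cutoff."""
    with open(path, "w") as fh:
        cols = "\t".join(f"c{c:g}" for c in ladder)
        fh.write(f"i\tj\td\t{cols}\n")
        for i in range(dm.n):
            for j in range(i + 1, dm.n):
                d = dm.d[i, j]
                flags = "\t".join("1" if d <= c else "0" for c in ladder)
                fh.write(f"{i + 1}\t{j + 1}\t{d:.3f}\t{flags}\n")
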