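"""Residue-residue contact maps and ensemble contact frequencies.

A contact between two MSA columns exists in a structure when the nearest
sidechain heavy-atom distance is strictly below the cutoff (default 6 Å).
Contact frequencies over an ensemble use per-pair denominators: structures in
which either residue is unresolved are excluded from that pair's count, so a
pair's frequency is (# structures in contact) / (# structures with both
residues resolved), and pairs never co-resolved are absent rather than zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Residue",
    "MappedStructure",
    "ContactMap",
    "ContactFrequencies",
    "DeltaContacts",
    "sidechain_min_distance",
    "contact_map",
    "contact_frequencies",
    "delta_contacts",
    "read_structure",
    "read_residue_map",
    "write_residue_map",
    "write_frequencies_tsv",
    "read_frequencies_tsv",
    "write_delta_tsv",
    "read_delta_tsv",
]

logger = logging.getLogger("kinothread")

#: Backbone heavy atoms excluded from the sidechain set.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Default nearest-sidechain heavy-atom contact cutoff, Å (strict "<").
DEFAULT_CUTOFF = 6.0


@dataclass
class Residue:
    """One mapped residue: name plus heavy-atom coordinates keyed by atom name."""

    name: str
    atoms: dict  # atom name -> (3,) float array, Å

    def sidechain_coords(self, gly_proxy: str = "CA") -> np.ndarray:
        """Sidechain heavy-atom coordinates, shape (n, 3).

        Backbone atoms (N, CA, C, O, OXT) are excluded.  Glycine, which has no
        sidechain heavy atom, falls back to the configurable proxy atom
        (default CA); any residue left with no usable atom does the same.
        """
        coords = [xyz for name, xyz in self.atoms.items()
                  if name not in BACKBONE_ATOMS and not name.startswith("H")]
        if not coords:
            proxy = self.atoms.get(gly_proxy)
            if proxy is None:
                return np.empty((0, 3))
            coords = [proxy]
        return np.asarray(coords, dtype=float)


@dataclass
class MappedStructure:
    """A chain with residues keyed by 1-based MSA column.

    ``missing_columns`` lists columns of the residue map that have no resolved
    residue in this structure (used for per-pair frequency denominators).
    """

    identifier: str
    chain: str
    residues: dict  # msa column (1-based int) -> Residue
    missing_columns: set = field(default_factory=set)

    def __post_init__(self):
        for col, res in self.residues.items():
            for name, xyz in res.atoms.items():
                arr = np.asarray(xyz, dtype=float)
                if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                    raise ValueError(
                        f"{self.identifier}: residue at column {col} atom {name} "
                        f"has invalid coordinates"
                    )
            if not res.atoms:
                raise ValueError(
                    f"{self.identifier}: residue at column {col} has no atoms"
                )

    @property
    def columns(self) -> list:
        return sorted(self.residues)


@dataclass
class ContactMap:
    """Unordered column pairs (i<j) judged in contact in one structure."""

    pairs: set

    def __contains__(self, pair) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs


@dataclass
class ContactFrequencies:
    """Per-pair contact probabilities over an ensemble.

    ``freq``/``count`` map (i, j) with i<j to the contact frequency and the
    number of structures where both columns were resolved; pairs never
    co-resolved are absent.
    """

    freq: dict   # (i, j) -> float in [0, 1]
    count: dict  # (i, j) -> int > 0
    n_structures: int
    L: int | None = None  # alignment length, when known

    def defined_pairs(self) -> set:
        return set(self.freq)

    def get(self, i: int, j: int):
        return self.freq.get((min(i, j), max(i, j)))


@dataclass
class DeltaContacts:
    """dc[i][j] = c_A[i][j] - c_B[i][j], defined only where both basins have counts."""

    dc: dict  # (i, j) i<j -> float in [-1, 1]

    def get(self, i: int, j: int):
        return self.dc.get((min(i, j), max(i, j)))

    def columns(self) -> set:
        out = set()
        for i, j in self.dc:
            out.add(i)
            out.add(j)
        return out


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def sidechain_min_distance(resA: Residue, resB: Residue,
                           gly_proxy: str = "CA") -> float:
    """Minimum Euclidean distance between the two residues' sidechain heavy atoms."""
    a = resA.sidechain_coords(gly_proxy)
    b = resB.sidechain_coords(gly_proxy)
    if a.size == 0 or b.size == 0:
        raise ValueError("residue with no usable atoms")
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def contact_map(structure: MappedStructure, cutoff: float = DEFAULT_CUTOFF,
                gly_proxy: str = "CA") -> ContactMap:
    """All resolved column pairs with nearest-sidechain distance strictly < cutoff."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if not structure.residues:
        raise ValueError(f"{structure.identifier}: structure has no mapped residues")
    cols = structure.columns
    coords = {}
    for c in cols:
        sc = structure.residues[c].sidechain_coords(gly_proxy)
        if sc.size == 0:
            logger.warning("%s: column %d has no usable atoms; pairs skipped",
                           structure.identifier, c)
            continue
        coords[c] = sc
    usable = sorted(coords)
    pairs = set()
    for ai, i in enumerate(usable):
        for j in usable[ai + 1:]:
            d = np.linalg.norm(coords[i][:, None, :] - coords[j][None, :, :],
                               axis=-1).min()
            if d < cutoff:
                pairs.add((i, j))
    return ContactMap(pairs=pairs)


def contact_frequencies(ensemble: list, cutoff: float = DEFAULT_CUTOFF,
                        gly_proxy: str = "CA",
                        L: int | None = None) -> ContactFrequencies:
    """Ensemble contact frequencies with per-pair resolved-structure denominators."""
    if not ensemble:
        raise ValueError("ensemble is empty")
    hits: dict = {}
    counts: dict = {}
    for st in ensemble:
        cmap = contact_map(st, cutoff=cutoff, gly_proxy=gly_proxy)
        cols = st.columns
        for ai, i in enumerate(cols):
            for j in cols[ai + 1:]:
                key = (i, j)
                counts[key] = counts.get(key, 0) + 1
                if key in cmap.pairs:
                    hits[key] = hits.get(key, 0) + 1
    freq = {key: hits.get(key, 0) / n for key, n in counts.items()}
    return ContactFrequencies(freq=freq, count=counts,
                              n_structures=len(ensemble), L=L)


def delta_contacts(freqA: ContactFrequencies,
                   freqB: ContactFrequencies) -> DeltaContacts:
    """dc = c_A - c_B on pairs defined in both basins; one-sided pairs are dropped."""
    if freqA.L is not None and freqB.L is not None and freqA.L != freqB.L:
        raise ValueError(
            f"alignment length mismatch between basins: {freqA.L} != {freqB.L}"
        )
    common = freqA.defined_pairs() & freqB.defined_pairs()
    only = freqA.defined_pairs() ^ freqB.defined_pairs()
    if only:
        logger.info("delta_contacts: %d pairs defined in only one basin dropped",
                    len(only))
    return DeltaContacts(dc={k: freqA.freq[k] - freqB.freq[k] for k in common})


# ---------------------------------------------------------------------------
# I/O: structures (gemmi), residue maps and frequency tables (TSV)
# ---------------------------------------------------------------------------

def read_residue_map(path) -> dict:
    """Residue→MSA-column map TSV: chain, resseq, icode, msa_column.

    Returns {(chain, resseq, icode): msa_column}; icode "-" or "" means none.
    """
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chain, resseq, icode, col = line.split("\t")
            icode = "" if icode in ("-", ".", "") else icode
            out[(chain, int(resseq), icode)] = int(col)
    return out


def write_residue_map(path, mapping: dict) -> None:
    with open(path, "w") as fh:
        fh.write("#chain\tresseq\ticode\tmsa_column\n")
        for (chain, resseq, icode), col in sorted(mapping.items(),
                                                  key=lambda kv: kv[1]):
            fh.write(f"{chain}\t{resseq}\t{icode or '-'}\t{col}\n")


def read_structure(path, residue_map: dict, chain: str | None = None,
                   identifier: str | None = None) -> MappedStructure:
    """Read a PDB/mmCIF file through gemmi into a :class:`MappedStructure`.

    Only residues listed in ``residue_map`` (keyed by chain/resseq/icode) are
    kept; map entries with no resolved residue become ``missing_columns``.
    Altlocs are resolved to the highest-occupancy conformer per atom name;
    hydrogens are discarded.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    wanted_chains = {c for (c, _, _) in residue_map}
    if chain is not None:
        wanted_chains &= {chain}
    residues = {}
    for ch in model:
        if ch.name not in wanted_chains:
            continue
        for res in ch:
            icode = res.seqid.icode.strip()
            key = (ch.name, res.seqid.num, icode)
            if key not in residue_map:
                continue
            col = residue_map[key]
            atoms: dict = {}
            occ: dict = {}
            for at in res:
                if at.is_hydrogen():
                    continue
                if at.name in atoms and occ.get(at.name, 0.0) >= at.occ:
                    continue
                atoms[at.name] = np.array([at.pos.x, at.pos.y, at.pos.z])
                occ[at.name] = at.occ
            if atoms:
                residues[col] = Residue(name=res.name, atoms=atoms)
    missing = set(residue_map.values()) - set(residues)
    return MappedStructure(
        identifier=identifier or str(path), chain=chain or "",
        residues=residues, missing_columns=missing,
    )


def write_frequencies_tsv(path, cf: ContactFrequencies) -> None:
    with open(path, "w") as fh:
        fh.write(f"#n_structures={cf.n_structures}\n")
        if cf.L is not None:
            fh.write(f"#L={cf.L}\n")
        fh.write("#i\tj\tfreq\tcount\n")
        for (i, j) in sorted(cf.freq):
            fh.write(f"{i}\t{j}\t{float(cf.freq[(i, j)])!r}\t{cf.count[(i, j)]}\n")


def read_frequencies_tsv(path) -> ContactFrequencies:
    freq, count, n, L = {}, {}, 0, None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#n_structures="):
                n = int(line.split("=", 1)[1])
                continue
            if line.startswith("#L="):
                L = int(line.split("=", 1)[1])
                continue
            if not line or line.startswith("#"):
                continue
            i, j, f, c = line.split("\t")
            freq[(int(i), int(j))] = float(f)
            count[(int(i), int(j))] = int(c)
    return ContactFrequencies(freq=freq, count=count, n_structures=n, L=L)


def write_delta_tsv(path, dc: DeltaContacts) -> None:
    with open(path, "w") as fh:
        fh.write("#i\tj\tdc\n")
        for (i, j) in sorted(dc.dc):
            fh.write(f"{i}\t{j}\t{float(dc.dc[(i, j)])!r}\n")


def read_delta_tsv(path) -> DeltaContacts:
    dc = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i, j, v = line.split("\t")
            dc[(int(i), int(j))] = float(v)
    return DeltaContacts(dc=dc)
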