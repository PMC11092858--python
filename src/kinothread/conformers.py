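"""Active/inactive basin assignment for kinase structures.

Structures carry externally supplied spatial DFG and dihedral-class labels
(KinCoRe-style).  Basin A (active) requires DFG-in + BLAminus; basin B
(inactive) requires DFG-out + BBAminus.  Both additionally require an αC-in
state (β3-Lys–αC-Glu salt bridge formed) and an extended glycine-rich loop
(G-loop Gly carbonyl O hydrogen-bonded to the β2 Val backbone N, while staying
clear of the pre-Phe amide N to exclude "kinked" loops).  Everything else is
rejected with a machine-readable reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .contacts import MappedStructure

__all__ = [
    "ConformerLabel",
    "FilterConfig",
    "gloop_extended",
    "alphaC_in",
    "classify_ensemble",
    "read_labels_tsv",
    "write_rejection_report",
]

logger = logging.getLogger("kinothread")

DFG_IN = "in"
DFG_OUT = "out"
ACTIVE_DIHEDRAL = "BLAminus"
INACTIVE_DIHEDRAL = "BBAminus"


@dataclass
class ConformerLabel:
    """External spatial/dihedral annotation for one structure."""

    spatial_dfg: str   # "in", "out", "other"
    dihedral_class: str  # e.g. "BLAminus", "BBAminus"
    source: str = "external"

    def __post_init__(self):
        if not self.spatial_dfg or not self.dihedral_class:
            raise ValueError("spatial_dfg and dihedral_class must be non-empty")


@dataclass
class FilterConfig:
    """Geometric filter thresholds (Å) and motif MSA columns (1-based).

    ``hbond_max`` bounds the G-loop Gly O – β2 Val N hydrogen bond;
    ``kink_min`` is the minimum Gly O – pre-Phe N distance required for a
    non-kinked loop; ``saltbridge_max`` bounds the Lys NZ – Glu OE distance.
    """

    hbond_max: float = 3.5
    kink_min: float = 6.5
    saltbridge_max: float = 4.0
    gloop_gly_col: int | None = None
    beta2_val_col: int | None = None
    prephe_col: int | None = None
    beta3_lys_col: int | None = None
    alphaC_glu_col: int | None = None
    apply_geometry: bool = True  # geometric filters can be switched off

    def __post_init__(self):
        for name in ("hbond_max", "kink_min", "saltbridge_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class IndeterminateFilter(Exception):
    """A geometric filter could not be evaluated (missing residue/atom)."""


def _atom(structure: MappedStructure, col: int | None, atom: str,
          what: str) -> np.ndarray:
    if col is None:
        raise IndeterminateFilter(f"{what}: motif column not configured")
    res = structure.residues.get(col)
    if res is None:
        raise IndeterminateFilter(f"{what}: column {col} unresolved")
    xyz = res.atoms.get(atom)
    if xyz is None:
        raise IndeterminateFilter(f"{what}: atom {atom} missing at column {col}")
    return np.asarray(xyz, dtype=float)


def gloop_extended(structure: MappedStructure, cfg: FilterConfig) -> bool:
    """Extended (non-kinked) glycine-rich loop test.

    True iff the backbone carbonyl O of the first conserved G-loop Gly is
    within ``hbond_max`` of the β2 Val backbone N *and* at least ``kink_min``
    from the amide N of the residue immediately before the conserved Phe/Tyr.
    """
    o = _atom(structure, cfg.gloop_gly_col, "O", "gloop Gly carbonyl")
    n_val = _atom(structure, cfg.beta2_val_col, "N", "beta2 Val amide")
    n_pre = _atom(structure, cfg.prephe_col, "N", "pre-Phe amide")
    hbond = float(np.linalg.norm(o - n_val))
    kink = float(np.linalg.norm(o - n_pre))
    return hbond < cfg.hbond_max and kink >= cfg.kink_min


def alphaC_in(structure: MappedStructure, cfg: FilterConfig) -> bool:
    """β3-Lys–αC-Glu salt bridge test: min NZ–OE distance ≤ ``saltbridge_max``."""
    nz = _atom(structure, cfg.beta3_lys_col, "NZ", "beta3 Lys NZ")
    glu = structure.residues.get(cfg.alphaC_glu_col) if cfg.alphaC_glu_col else None
    if glu is None:
        raise IndeterminateFilter(
            f"alphaC Glu: column {cfg.alphaC_glu_col} unresolved"
        )
    oxygens = [np.asarray(glu.atoms[a], dtype=float)
               for a in ("OE1", "OE2") if a in glu.atoms]
    if not oxygens:
        raise IndeterminateFilter("alphaC Glu: no carboxylate oxygen atoms")
    dmin = min(float(np.linalg.norm(nz - o)) for o in oxygens)
    return dmin <= cfg.saltbridge_max


def classify_ensemble(structures: list, labels: dict, cfg: FilterConfig):
    """Partition structures into (basinA, basinB, rejected-with-reason).

    ``labels`` maps structure identifier -> :class:`ConformerLabel`.  Basin A
    requires DFG-in/BLAminus, basin B DFG-out/BBAminus, and (when
    ``cfg.apply_geometry``) both require the salt-bridge and extended-G-loop
    filters.  Every input lands in exactly one of the three outputs.
    """
    basinA, basinB, rejected = [], [], []
    for st in structures:
        label = labels.get(st.identifier)
        if label is None:
            rejected.append((st, "no_label"))
            continue
        if label.spatial_dfg == DFG_IN and label.dihedral_class == ACTIVE_DIHEDRAL:
            target = basinA
        elif (label.spatial_dfg == DFG_OUT
              and label.dihedral_class == INACTIVE_DIHEDRAL):
            target = basinB
        else:
            rejected.append(
                (st, f"class_{label.spatial_dfg}_{label.dihedral_class}")
            )
            continue
        if cfg.apply_geometry:
            try:
                if not alphaC_in(st, cfg):
                    rejected.append((st, "saltbridge_fail"))
                    continue
                if not gloop_extended(st, cfg):
                    rejected.append((st, "gloop_fail"))
                    continue
            except IndeterminateFilter as exc:
                logger.warning("%s excluded: %s", st.identifier, exc)
                rejected.append((st, f"indeterminate:{exc}"))
                continue
        target.append(st)
    return basinA, basinB, rejected


def read_labels_tsv(path) -> dict:
    """Labels TSV: structure_id, chain, spatial_dfg, dihedral_class."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, _chain, spatial, dihedral = line.split("\t")
            out[sid] = ConformerLabel(spatial_dfg=spatial, dihedral_class=dihedral)
    return out


def write_rejection_report(path, rejected: list) -> None:
    with open(path, "w") as fh:
        fh.write("#structure_id\treason\n")
        for st, reason in rejected:
            fh.write(f"{st.identifier}\t{reason}\n")
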