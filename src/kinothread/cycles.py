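"""Double-mutant thermodynamic-cycle bookkeeping for mutation free energies.

For a mutation w→m performed alchemically in two conformational basins,

    ΔΔG_reorg = ΔG_B(w→m) - ΔG_A(w→m)

with the same sign convention as ΔΔT: positive favours the active basin A.
For a double mutation {i, j} there are three thermodynamically equivalent
paths to the double mutant (via i, via j, or simultaneously); their spread
(population standard deviation) estimates hysteresis.  The double-mutant
cycle likewise gives three estimates for each constituent single.  The
Potts↔FEP comparison regresses ΔΔG_reorg on ΔΔT: the slope is the
statistical-energy → kcal/mol conversion factor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AlchemicalLeg",
    "CycleResult",
    "plan_jobs",
    "ddg_reorg",
    "close_cycles",
    "compare_potts_fep",
    "population_from_dg",
    "read_legs_tsv",
    "write_legs_tsv",
]

logger = logging.getLogger("kinothread")

BASINS = ("A", "B")
#: Boltzmann constant in kcal/(mol·K).
KB_KCAL = 0.0019872

WT = "wt"


@dataclass(frozen=True)
class AlchemicalLeg:
    """One alchemical ΔG leg: start variant → end variant in one basin."""

    kinase: str
    basin: str
    start: str  # variant label, e.g. "wt", "i", "j", "ij"
    end: str
    dg: float       # kcal/mol
    dg_err: float = 0.0

    def __post_init__(self):
        if self.basin not in BASINS:
            raise ValueError(f"basin must be one of {BASINS}, got {self.basin!r}")
        if self.start == self.end:
            raise ValueError("leg start and end variants must differ")
        if self.dg_err < 0:
            raise ValueError("dg_err must be >= 0")


@dataclass
class CycleResult:
    """Per-path ΔΔG_reorg estimates for one variant of a double-mutant cycle."""

    mutation: str
    paths: list            # up to 3 path estimates, kcal/mol
    mean: float
    path_std: float | None  # population std; None when only one path
    paths_used: int

    @classmethod
    def from_paths(cls, mutation: str, paths: list) -> "CycleResult":
        if not paths:
            raise ValueError(f"{mutation}: no available path")
        arr = np.asarray(paths, dtype=float)
        std = float(arr.std(ddof=0)) if len(arr) > 1 else None
        return cls(mutation=mutation, paths=list(map(float, paths)),
                   mean=float(arr.mean()), path_std=std, paths_used=len(arr))


# ---------------------------------------------------------------------------
# Job planning
# ---------------------------------------------------------------------------

def plan_jobs(selections: dict, include_closure: bool = False) -> list:
    """FEP job manifest for per-kinase double-mutation selections.

    ``selections`` maps kinase id -> list of double-mutation labels (i, j)
    (any hashable pair; typically the two single-substitution strings).  The
    core set per double is the legs w→i, w→j, w→ij in each basin; with
    ``include_closure`` the single→double legs i→ij and j→ij are added.
    Rows are (kinase, basin, start, end, double_label), unique and in
    deterministic order; duplicate selections are deduplicated with a warning.
    """
    manifest = []
    seen = set()
    for kinase in sorted(selections):
        for double in selections[kinase]:
            i, j = double
            key = (kinase, i, j)
            if key in seen:
                logger.warning("duplicate selection %s dropped", key)
                continue
            seen.add(key)
            label = f"{i}+{j}"
            legs = [(WT, str(i)), (WT, str(j)), (WT, label)]
            if include_closure:
                legs += [(str(i), label), (str(j), label)]
            for basin in BASINS:
                for start, end in legs:
                    manifest.append((kinase, basin, start, end, label))
    return manifest


# ---------------------------------------------------------------------------
# ΔΔG_reorg and cycle closure
# ---------------------------------------------------------------------------

def ddg_reorg(legs: list) -> float:
    """ΔΔG_reorg = ΔG_B - ΔG_A for one variant's pair of basin legs."""
    by_basin = {}
    for leg in legs:
        by_basin[leg.basin] = leg
    for basin in BASINS:
        if basin not in by_basin:
            raise ValueError(f"missing leg for basin {basin}")
    return float(by_basin["B"].dg - by_basin["A"].dg)


def _path_sums(dg: dict, paths: list):
    """Evaluate per-basin path sums; returns ΔΔG (B-A) per available path."""
    out = []
    for path in paths:
        ok = all(term in dg["A"] and term in dg["B"] for term, _ in path)
        if not ok:
            continue
        per_basin = {}
        for basin in BASINS:
            per_basin[basin] = sum(sign * dg[basin][term] for term, sign in path)
        out.append(per_basin["B"] - per_basin["A"])
    return out


def close_cycles(legs: list, mutation: str = "") -> dict:
    """Three-path cycle closure for one double mutation's legs.

    ``legs`` holds :class:`AlchemicalLeg` records for one kinase and one
    double {i, j}, with variant labels "wt", the two single labels and the
    double label "i+j".  Paths for the double: (w→i)+(i→ij), (w→j)+(j→ij),
    and the direct (w→ij).  Paths for single i: direct (w→i);
    (w→ij)−(i→ij); and (w→j)+(j→ij)−(i→ij) (symmetrically for j).  Each path
    is evaluated per basin, then differenced B−A.  Returns
    {"double": CycleResult, "single_i": CycleResult, "single_j": CycleResult}
    over available paths; with additive noise-free legs all paths agree
    exactly.
    """
    doubles = sorted({leg.end for leg in legs if "+" in leg.end})
    if len(doubles) != 1:
        raise ValueError(f"expected legs for exactly one double, got {doubles}")
    dbl = doubles[0]
    i_lab, j_lab = dbl.split("+", 1)

    dg = {"A": {}, "B": {}}
    for leg in legs:
        dg[leg.basin][(leg.start, leg.end)] = leg.dg

    w_i, w_j, w_d = (WT, i_lab), (WT, j_lab), (WT, dbl)
    i_d, j_d = (i_lab, dbl), (j_lab, dbl)

    double_paths = [
        [(w_i, +1), (i_d, +1)],
        [(w_j, +1), (j_d, +1)],
        [(w_d, +1)],
    ]
    single_i_paths = [
        [(w_i, +1)],
        [(w_d, +1), (i_d, -1)],
        [(w_j, +1), (j_d, +1), (i_d, -1)],
    ]
    single_j_paths = [
        [(w_j, +1)],
        [(w_d, +1), (j_d, -1)],
        [(w_i, +1), (i_d, +1), (j_d, -1)],
    ]

    name = mutation or dbl
    return {
        "double": CycleResult.from_paths(name, _path_sums(dg, double_paths)),
        "single_i": CycleResult.from_paths(i_lab, _path_sums(dg, single_i_paths)),
        "single_j": CycleResult.from_paths(j_lab, _path_sums(dg, single_j_paths)),
    }


# ---------------------------------------------------------------------------
# Potts ↔ FEP comparison and population conversion
# ---------------------------------------------------------------------------

def compare_potts_fep(pairs: list) -> dict:
    """Pearson r (two-sided p) and OLS of ΔΔG_reorg on ΔΔT.

    ``pairs`` is a sequence of (ΔΔT, ΔΔG_reorg).  The regression slope is the
    statistical-energy → kcal/mol conversion factor; the p-value uses the
    t-transform of r.  Also returns the slope standard error for CIs.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (ddT, ddG) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in ddT or ddG values")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return {
        "n": int(len(x)),
        "pearson_r": float(r),
        "p_value": float(p),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "slope_stderr": float(fit.stderr),
    }


def population_from_dg(dg: float, temperature: float = 300.0) -> float:
    """Inactive-state fraction for a free-energy gap ΔG (kcal/mol, active lower).

    fraction = exp(-ΔG/kT) / (1 + exp(-ΔG/kT)); ΔG = 1.3 kcal/mol at 300 K
    gives ≈0.10, i.e. a 1:10 inactive:active ratio.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    if not math.isfinite(dg):
        raise ValueError("dg must be finite")
    kT = KB_KCAL * temperature
    z = math.exp(-dg / kT) if dg > -700 * kT else math.inf
    if math.isinf(z):
        return 1.0
    return z / (1.0 + z)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_legs_tsv(path) -> list:
    """Legs TSV: kinase, basin, start, end, dg, dg_err."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            kinase, basin, start, end, dg, err = line.split("\t")
            out.append(AlchemicalLeg(kinase=kinase, basin=basin, start=start,
                                     end=end, dg=float(dg), dg_err=float(err)))
    return out


def write_legs_tsv(path, legs: list) -> None:
    with open(path, "w") as fh:
        fh.write("#kinase\tbasin\tstart\tend\tdg\tdg_err\n")
        for leg in legs:
            fh.write(f"{leg.kinase}\t{leg.basin}\t{leg.start}\t{leg.end}\t"
                     f"{float(leg.dg)!r}\t{float(leg.dg_err)!r}\n")
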