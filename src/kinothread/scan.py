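"""Mutational scanning of the conformational preference ΔT.

The scan enumerates single and double substitutions at columns that (a) do
not carry Gly, Pro, Trp, His, or Cys (or a gap) as wildtype and (b) take part
in at least one contact change with |Δc| above a threshold (default 0.8), so
only positions whose physicochemical environment changes between basins are
scanned.  The same residues are barred as mutation targets.  Double mutations
pair eligible columns whose mutual |Δc| passes the gate (configurable to all
eligible×eligible pairs).  The most extreme ΔΔT rows of each tail are
selected for free-energy follow-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import DeltaContacts
from .potts import GAP, AlignedSequence, PottsModel
from .threader import MutationSpec, Substitution, delta_T, delta_delta_T

__all__ = [
    "ScanConfig",
    "ScanTable",
    "eligible_positions",
    "enumerate_mutations",
    "run_scan",
    "select_tails",
]

logger = logging.getLogger("kinothread")

#: Residues excluded both as wildtype and as mutation targets: backbone
#: flexibility (G, P), bulk (W), tautomer/disulfide ambiguity (H, C).
EXCLUDED_RESIDUES = frozenset("GPWHC")


@dataclass
class ScanConfig:
    excluded_residues: frozenset = EXCLUDED_RESIDUES
    dc_threshold: float = 0.8
    n_left_tail: int = 3
    n_right_tail: int = 3
    pair_rule: str = "dc_gated"  # or "all_eligible"

    def __post_init__(self):
        if not 0 < self.dc_threshold <= 1:
            raise ValueError("dc_threshold must be in (0, 1]")
        if self.n_left_tail < 0 or self.n_right_tail < 0:
            raise ValueError("tail sizes must be >= 0")
        if self.pair_rule not in ("dc_gated", "all_eligible"):
            raise ValueError(f"unknown pair_rule {self.pair_rule!r}")
        self.excluded_residues = frozenset(self.excluded_residues)


@dataclass
class ScanTable:
    """One row per mutation: (MutationSpec, ΔΔT, ΔT_mut = ΔΔT + ΔT_wt)."""

    rows: pd.DataFrame  # columns: mutation (MutationSpec), ddT, dT_mut
    delta_T_wt: float

    def __len__(self) -> int:
        return len(self.rows)


def eligible_positions(wt: AlignedSequence | str, dc: DeltaContacts,
                       cfg: ScanConfig) -> set:
    """1-based columns eligible for mutation.

    A column is eligible iff its wildtype residue is allowed (not excluded,
    not a gap) and it participates in at least one pair with |dc| strictly
    above the threshold.
    """
    symbols = wt.symbols if isinstance(wt, AlignedSequence) else wt
    hot = set()
    for (i, j), d in dc.dc.items():
        if abs(d) > cfg.dc_threshold:
            hot.add(i)
            hot.add(j)
    out = set()
    for col in hot:
        aa = symbols[col - 1]
        if aa == GAP or aa in cfg.excluded_residues:
            continue
        out.add(col)
    return out


def _allowed_targets(alphabet: str, wt_state: str, cfg: ScanConfig) -> list:
    return [a for a in alphabet
            if a != wt_state and a != GAP and a not in cfg.excluded_residues]


def enumerate_mutations(wt: AlignedSequence | str, eligible: set,
                        dc: DeltaContacts, cfg: ScanConfig,
                        alphabet: str) -> list:
    """All single and double mutations over the eligible columns.

    Singles cross every eligible column with every allowed target state;
    doubles cross pairs of eligible columns (gated by |dc| > threshold under
    the default pair rule) with allowed target-state pairs.  Ordering is
    deterministic: singles by (column, target), then doubles by (i, j,
    target_i, target_j) in alphabet order.
    """
    symbols = wt.symbols if isinstance(wt, AlignedSequence) else wt
    cols = sorted(eligible)
    out: list = []
    for c in cols:
        for a in _allowed_targets(alphabet, symbols[c - 1], cfg):
            out.append(MutationSpec((Substitution(c, symbols[c - 1], a),)))
    for ci in range(len(cols)):
        for cj in range(ci + 1, len(cols)):
            i, j = cols[ci], cols[cj]
            if cfg.pair_rule == "dc_gated":
                d = dc.get(i, j)
                if d is None or abs(d) <= cfg.dc_threshold:
                    continue
            for a in _allowed_targets(alphabet, symbols[i - 1], cfg):
                for b in _allowed_targets(alphabet, symbols[j - 1], cfg):
                    out.append(MutationSpec((
                        Substitution(i, symbols[i - 1], a),
                        Substitution(j, symbols[j - 1], b),
                    )))
    return out


def run_scan(model: PottsModel, wt: AlignedSequence | str, mutations: list,
             dc: DeltaContacts) -> ScanTable:
    """Score ΔΔT for every mutation (sparse evaluation) plus ΔT_mut bookkeeping.

    Per-column coupling·dc profiles are precomputed so each single costs one
    vector lookup and each double adds a single interaction correction; the
    result matches a dense two-sequence recomputation exactly.
    """
    symbols = wt.symbols if isinstance(wt, AlignedSequence) else wt
    s_w = model.encode(symbols)
    dT_wt = delta_T(model, symbols, dc).delta_T

    # profile[c][a] = ΔΔT of the single mutation col c -> state a
    cols = sorted({c for m in mutations for c in m.columns})
    idx = {ch: k for k, ch in enumerate(model.alphabet)}
    profile = {c: np.zeros(model.q) for c in cols}
    colset = set(cols)
    pair_dc = {}
    for (i, j), d in dc.dc.items():
        blk = model.J(i - 1, j - 1)
        if i in colset:
            profile[i] += -(blk[:, s_w[j - 1]] - blk[s_w[i - 1], s_w[j - 1]]) * d
        if j in colset:
            profile[j] += -(blk[s_w[i - 1], :] - blk[s_w[i - 1], s_w[j - 1]]) * d
        if i in colset and j in colset:
            pair_dc[(i, j)] = (blk, d)

    ddts = np.empty(len(mutations))
    for k, m in enumerate(mutations):
        subs = m.substitutions
        for s0 in subs:
            if symbols[s0.column - 1] != s0.from_state:
                raise ValueError(
                    f"mutation {m}: wildtype at column {s0.column} is "
                    f"{symbols[s0.column - 1]!r}, not {s0.from_state!r}"
                )
        if len(subs) == 1:
            s0 = subs[0]
            ddts[k] = profile[s0.column][idx[s0.to_state]]
        else:
            si, sj = subs
            val = (profile[si.column][idx[si.to_state]]
                   + profile[sj.column][idx[sj.to_state]])
            hit = pair_dc.get((si.column, sj.column))
            if hit is not None:
                blk, d = hit
                a, b = idx[si.to_state], idx[sj.to_state]
                wi, wj = s_w[si.column - 1], s_w[sj.column - 1]
                # the (i,j) pair was corrected twice via the single profiles
                val += -(blk[a, b] - blk[a, wj] - blk[wi, b] + blk[wi, wj]) * d
            ddts[k] = val

    df = pd.DataFrame({
        "mutation": mutations,
        "ddT": ddts,
        "dT_mut": ddts + dT_wt,
    })
    if df["mutation"].map(str).duplicated().any():
        raise ValueError("duplicate MutationSpec rows in scan input")
    return ScanTable(rows=df, delta_T_wt=dT_wt)


def select_tails(table: ScanTable, cfg: ScanConfig) -> list:
    """The n most-negative plus n most-positive ΔΔT mutations.

    Ties are broken by |ΔΔT| then by lexicographic mutation key, making the
    selection deterministic.  If the table is smaller than the request, all
    rows are returned with a warning.
    """
    if len(table) == 0:
        raise ValueError("scan table is empty")
    want = cfg.n_left_tail + cfg.n_right_tail
    recs = list(zip(table.rows["mutation"], table.rows["ddT"]))
    if len(recs) <= want:
        logger.warning("scan table has %d rows < %d requested; returning all",
                       len(recs), want)
        return [m for m, _ in sorted(recs, key=lambda r: (r[1], r[0].sort_key()))]
    left = sorted(recs, key=lambda r: (r[1], abs(r[1]), r[0].sort_key()))
    right = sorted(recs, key=lambda r: (-r[1], abs(r[1]), r[0].sort_key()))
    chosen = left[:cfg.n_left_tail] + right[:cfg.n_right_tail]
    return [m for m, _ in chosen]
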