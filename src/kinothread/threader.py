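"""Threading Potts couplings over structures and ensembles: ΔT and ΔΔT.

Threading sums a sequence's couplings over the residue contacts of a
structure (or, for an ensemble, weights them by contact frequency).  The
conformational preference of a sequence between an active basin A and an
inactive basin B is

    ΔT(S) = T_B(S) - T_A(S) = -Σ_{i<j} J[i][j][S_i][S_j] · Δc_ij,
    Δc_ij = c_A_ij - c_B_ij,

so positive ΔT penalises the inactive basin.  ΔΔT(w→m) = ΔT(m) - ΔT(w) is the
mutational shift in that preference; positive values shift the balance toward
the active conformation.  Threading sums raw couplings and is not gauge
invariant, so a zero-mean-gauge model is required (fields never contribute).

MSA columns in contact-map/frequency objects are 1-based; Potts positions are
0-based, so column ``c`` threads coupling position ``c - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import ContactFrequencies, ContactMap, DeltaContacts
from .potts import AlignedSequence, PottsModel

__all__ = [
    "ThreadingResult",
    "MutationSpec",
    "Substitution",
    "thread_structure",
    "thread_ensemble",
    "thread_basins",
    "delta_T",
    "delta_delta_T",
    "pair_decomposition",
]


@dataclass(frozen=True, order=True)
class Substitution:
    """One substitution at a 1-based MSA column."""

    column: int
    from_state: str
    to_state: str

    def __str__(self) -> str:
        return f"{self.from_state}{self.column}{self.to_state}"


@dataclass(frozen=True)
class MutationSpec:
    """One single or double substitution (columns distinct)."""

    substitutions: tuple

    def __post_init__(self):
        subs = tuple(sorted(self.substitutions))
        object.__setattr__(self, "substitutions", subs)
        if not 1 <= len(subs) <= 2:
            raise ValueError("MutationSpec holds 1 or 2 substitutions")
        cols = [s.column for s in subs]
        if len(set(cols)) != len(cols):
            raise ValueError("substitution columns must be distinct")

    @property
    def columns(self) -> tuple:
        return tuple(s.column for s in self.substitutions)

    def sort_key(self) -> tuple:
        return tuple((s.column, s.to_state, s.from_state)
                     for s in self.substitutions)

    def __str__(self) -> str:
        return "+".join(str(s) for s in self.substitutions)

    def apply(self, symbols: str) -> str:
        out = list(symbols)
        for s in self.substitutions:
            if out[s.column - 1] != s.from_state:
                raise ValueError(
                    f"wildtype state at column {s.column} is "
                    f"{out[s.column - 1]!r}, mutation expects {s.from_state!r}"
                )
            out[s.column - 1] = s.to_state
        return "".join(out)

    def reversed(self) -> "MutationSpec":
        return MutationSpec(tuple(
            Substitution(s.column, s.to_state, s.from_state)
            for s in self.substitutions
        ))


@dataclass
class ThreadingResult:
    """ΔT between two basins with its per-pair contribution decomposition.

    ``contributions`` holds (i, j, -J[i][j][s_i][s_j]·dc_ij) for every pair
    with defined dc; they sum exactly to ``delta_T``.
    """

    T_A: float | None
    T_B: float | None
    delta_T: float
    contributions: list  # (i, j, value), 1-based columns


def _require_zero_mean(model: PottsModel) -> None:
    if not model.is_zero_mean():
        raise ValueError(
            "threading requires a zero-mean gauge model (fields do not "
            "contribute); run to_zero_mean_gauge first"
        )


def thread_structure(model: PottsModel, seq: AlignedSequence | str,
                     cmap: ContactMap) -> float:
    """Threaded energy over one structure: Σ over contacts of J[i][j][s_i][s_j]."""
    _require_zero_mean(model)
    symbols = seq.symbols if isinstance(seq, AlignedSequence) else seq
    s = model.encode(symbols)
    total = 0.0
    for (i, j) in cmap.pairs:
        total += model.J(i - 1, j - 1)[s[i - 1], s[j - 1]]
    return float(total)


def thread_ensemble(model: PottsModel, seq: AlignedSequence | str,
                    freqs: ContactFrequencies) -> float:
    """Ensemble-average threaded energy: Σ_{i<j} J[i][j][s_i][s_j]·c_ij."""
    _require_zero_mean(model)
    symbols = seq.symbols if isinstance(seq, AlignedSequence) else seq
    s = model.encode(symbols)
    total = 0.0
    for (i, j), f in freqs.freq.items():
        total += model.J(i - 1, j - 1)[s[i - 1], s[j - 1]] * f
    return float(total)


def delta_T(model: PottsModel, seq: AlignedSequence | str,
            dc: DeltaContacts) -> ThreadingResult:
    """ΔT = T_B - T_A = -Σ_{i<j} J[i][j][s_i][s_j]·dc_ij over defined pairs."""
    _require_zero_mean(model)
    symbols = seq.symbols if isinstance(seq, AlignedSequence) else seq
    s = model.encode(symbols)
    contributions = []
    for (i, j), d in dc.dc.items():
        contributions.append(
            (i, j, float(-model.J(i - 1, j - 1)[s[i - 1], s[j - 1]] * d))
        )
    total = float(sum(v for _, _, v in contributions))
    return ThreadingResult(T_A=None, T_B=None, delta_T=total,
                           contributions=contributions)


def thread_basins(model: PottsModel, seq: AlignedSequence | str,
                  freqA: ContactFrequencies,
                  freqB: ContactFrequencies) -> ThreadingResult:
    """Thread one sequence over both basins; ΔT and contributions come from dc.

    T_A and T_B are ensemble-threaded energies over each basin's frequencies;
    the decomposition (and the ΔT it sums to) is restricted to pairs with
    defined dc, i.e. pairs co-resolved in both basins.
    """
    from .contacts import delta_contacts

    t_a = thread_ensemble(model, seq, freqA)
    t_b = thread_ensemble(model, seq, freqB)
    res = delta_T(model, seq, delta_contacts(freqA, freqB))
    return ThreadingResult(T_A=t_a, T_B=t_b, delta_T=res.delta_T,
                           contributions=res.contributions)


def delta_delta_T(model: PottsModel, wt: AlignedSequence | str,
                  mut: MutationSpec, dc: DeltaContacts) -> float:
    """ΔΔT = ΔT(mutant) - ΔT(wildtype), computed sparsely.

    Only pairs touching a mutated column can change, so the sum runs over
    those pairs alone; the pair between two mutated columns is counted once.
    The wildtype state of each substitution is checked against ``wt``.
    """
    _require_zero_mean(model)
    symbols = wt.symbols if isinstance(wt, AlignedSequence) else wt
    m_symbols = mut.apply(symbols)  # validates from_state
    s_w = model.encode(symbols)
    s_m = model.encode(m_symbols)
    mut_cols = set(mut.columns)
    total = 0.0
    for (i, j), d in dc.dc.items():
        if i not in mut_cols and j not in mut_cols:
            continue
        blk = model.J(i - 1, j - 1)
        total += -(blk[s_m[i - 1], s_m[j - 1]] - blk[s_w[i - 1], s_w[j - 1]]) * d
    return float(total)


def pair_decomposition(result: ThreadingResult, top_k: int | None = None) -> list:
    """Contributions ranked by |value| descending; ties broken by (i, j)."""
    ranked = sorted(result.contributions, key=lambda t: (-abs(t[2]), t[0], t[1]))
    return ranked if top_k is None else ranked[:top_k]
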