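"""MSA filtering, identity down-weighting, weighted marginals, clade labels.

Sequences similar to many others are down-weighted by the standard
direct-coupling-analysis rule: the weight of a sequence is the reciprocal of
the number of sequences (itself included) with fractional identity at or
above a threshold (default 0.6, i.e. "within 40% identity").  Gaps count as a
21st symbol both in identity and in the marginals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .potts import ALPHABET, GAP, AlignedSequence

__all__ = [
    "WeightedMSA",
    "CladeRules",
    "filter_msa",
    "sequence_weights",
    "weighted_frequencies",
    "classify_clade",
    "DEFAULT_CLADE_RULES",
]


@dataclass
class WeightedMSA:
    sequences: list          # of AlignedSequence
    weights: np.ndarray      # per-sequence, in (0, 1]
    meff: float              # sum of weights

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.sequences):
            raise ValueError("one weight per sequence required")
        if np.any(self.weights <= 0) or np.any(self.weights > 1):
            raise ValueError("weights must be in (0, 1]")


@dataclass
class CladeRules:
    """Ordered conjunctive sequence constraints per clade label.

    ``rules`` is a list of (label, [(msa_column_1based, allowed_residue_set),
    ...]); the first clade whose constraints are all satisfied wins.
    """

    rules: list

    def labels(self) -> list:
        return [label for label, _ in self.rules]


#: Default clade rules, keyed to the catalytic-loop/activation-loop motif
#: contrasts between Tyr kinases and Ser/Thr kinases (catalytic base Arg at
#: HRD+4 and Pro at APE-5 for TKs, catalytic base Lys at HRD+2 for STKs), at
#: the reference MSA numbering (HRD Arg = column 123, APE-5 = column 162).
#: These are a configurable starting point; real analyses should supply the
#: columns matching their own alignment.
DEFAULT_CLADE_RULES = CladeRules(rules=[
    ("TK", [(128, {"R"}), (162, {"P"})]),
    ("STK", [(126, {"K"})]),
])


def filter_msa(msa: list, dfg_asp_column: int,
               max_gap_fraction: float = 0.25) -> list:
    """Drop gapped-DFG-Asp sequences, overly gappy sequences, and exact duplicates.

    The first occurrence of a duplicated symbol string is retained; order is
    otherwise preserved.
    """
    seen = set()
    out = []
    for s in msa:
        if dfg_asp_column > len(s.symbols):
            raise ValueError(
                f"dfg_asp_column {dfg_asp_column} exceeds alignment length "
                f"{len(s.symbols)}"
            )
        if s.symbols[dfg_asp_column - 1] == GAP:
            continue
        if s.symbols.count(GAP) / len(s.symbols) > max_gap_fraction:
            continue
        if s.symbols in seen:
            continue
        seen.add(s.symbols)
        out.append(s)
    return out


def _encode(msa: list, alphabet: str) -> np.ndarray:
    idx = {c: k for k, c in enumerate(alphabet)}
    try:
        return np.array([[idx[c] for c in s.symbols] for s in msa], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"symbol {exc} not in alphabet") from None


def sequence_weights(msa: list, identity_threshold: float = 0.6,
                     alphabet: str = ALPHABET) -> WeightedMSA:
    """DCA-style down-weighting: w_s = 1 / #{t : identity(s, t) >= threshold}.

    The neighbourhood includes the sequence itself, so weights lie in (0, 1]
    and the effective count Meff = Σ w never exceeds N.  Identity counts gap
    matches like any other symbol.
    """
    if not msa:
        raise ValueError("empty MSA")
    X = _encode(msa, alphabet)
    N, L = X.shape
    neighbours = np.zeros(N, dtype=int)
    # O(N^2 L) block comparison; fine at the corpus sizes this package handles
    for s in range(N):
        ident = (X == X[s]).mean(axis=1)
        neighbours[s] = int(np.count_nonzero(ident >= identity_threshold))
    weights = 1.0 / neighbours
    return WeightedMSA(sequences=list(msa), weights=weights,
                       meff=float(weights.sum()))


def weighted_frequencies(wmsa: WeightedMSA, alphabet: str = ALPHABET,
                         pairs: list | None = None):
    """Weighted single-site and pairwise marginals.

    Returns ``(f1, f2)``: ``f1[i, a] = Σ_s w_s·1[s_i = a] / Σ_s w_s`` of shape
    (L, q), and ``f2`` a dict mapping (i, j) 0-based with i<j to the q×q
    pairwise table (all pairs by default, or just ``pairs``).  Every site and
    pair table sums to 1.
    """
    X = _encode(wmsa.sequences, alphabet)
    N, L = X.shape
    q = len(alphabet)
    w = wmsa.weights / wmsa.weights.sum()
    f1 = np.zeros((L, q))
    for a in range(q):
        f1[:, a] = ((X == a) * w[:, None]).sum(axis=0)
    if pairs is None:
        pairs = [(i, j) for i in range(L) for j in range(i + 1, L)]
    f2 = {}
    for (i, j) in pairs:
        tab = np.zeros((q, q))
        np.add.at(tab, (X[:, i], X[:, j]), w)
        f2[(i, j)] = tab
    return f1, f2


def classify_clade(seq: AlignedSequence | str,
                   rules: CladeRules = DEFAULT_CLADE_RULES) -> str:
    """First clade label whose column constraints are all satisfied, else
    ``"unclassified"``."""
    symbols = seq.symbols if isinstance(seq, AlignedSequence) else seq
    for label, constraints in rules.rules:
        ok = True
        for col, allowed in constraints:
            if col > len(symbols):
                raise ValueError(f"rule column {col} exceeds sequence length")
            if symbols[col - 1] not in allowed:
                ok = False
                break
        if ok:
            return label
    return "unclassified"
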