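"""Potts Hamiltonian: representation, statistical energy, gauge, and MCMC sampling.

A Potts model over an alignment of ``L`` columns and ``q`` states assigns each
aligned sequence ``S`` the statistical energy

    E(S) = sum_{i<j} J[i][j][S_i][S_j] + sum_i h[i][S_i]

so that sequences are distributed as ``P(S) ∝ exp(-E(S))``.  Couplings are
stored densely for the ``i < j`` upper triangle only; the ``(j, i)`` view is
the transpose of the stored block.  The gap character is a full Potts state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ALPHABET",
    "GAP",
    "PottsModel",
    "AlignedSequence",
    "total_energy",
    "to_zero_mean_gauge",
    "sample_sequences",
    "read_fasta",
    "write_fasta",
    "read_stockholm",
    "write_stockholm",
    "save_model",
    "load_model",
    "write_couplings_text",
    "read_couplings_text",
]

#: Canonical state order: the 20 amino acids in one-letter alphabetical order,
#: followed by the gap symbol.  The gap is an ordinary 21st Potts state.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"
GAP = "-"

GAUGE_FIELDLESS = "fieldless"
GAUGE_ZERO_MEAN = "zero_mean"
GAUGE_OTHER = "other"

#: Absolute tolerance for gauge invariants.
GAUGE_ATOL = 1e-8


def _n_pairs(L: int) -> int:
    return L * (L - 1) // 2


def pair_index(i: int, j: int, L: int) -> int:
    """Flat index of pair (i, j), i < j, into the upper-triangle coupling array."""
    if not 0 <= i < j < L:
        raise ValueError(f"pair ({i}, {j}) is not an i<j pair for L={L}")
    return i * L - i * (i + 1) // 2 + (j - i - 1)


@dataclass
class PottsModel:
    """Couplings and fields over ``L`` positions × ``q`` states.

    Parameters
    ----------
    L, q
        Number of aligned columns and alphabet size.
    alphabet
        Ordered string of ``q`` distinct symbols.
    couplings
        Array of shape ``(L*(L-1)//2, q, q)``: ``couplings[pair_index(i,j,L), a, b]``
        is ``J[i][j][a][b]`` for ``i < j``.
    fields
        Array of shape ``(L, q)``.
    gauge_tag
        One of ``fieldless``, ``zero_mean``, ``other``.
    """

    L: int
    q: int = 21
    alphabet: str = ALPHABET
    couplings: np.ndarray = None
    fields: np.ndarray = None
    gauge_tag: str = GAUGE_OTHER

    def __post_init__(self):
        if self.L < 2:
            raise ValueError(f"L must be >= 2, got {self.L}")
        if self.q < 2:
            raise ValueError(f"q must be >= 2, got {self.q}")
        if len(self.alphabet) != self.q or len(set(self.alphabet)) != self.q:
            raise ValueError(
                f"alphabet must have exactly q={self.q} distinct symbols, "
                f"got {self.alphabet!r}"
            )
        P = _n_pairs(self.L)
        if self.couplings is None:
            self.couplings = np.zeros((P, self.q, self.q))
        self.couplings = np.asarray(self.couplings, dtype=float)
        if self.couplings.shape != (P, self.q, self.q):
            raise ValueError(
                f"couplings must have shape {(P, self.q, self.q)}, "
                f"got {self.couplings.shape}"
            )
        if self.fields is None:
            self.fields = np.zeros((self.L, self.q))
        self.fields = np.asarray(self.fields, dtype=float)
        if self.fields.shape != (self.L, self.q):
            raise ValueError(
                f"fields must have shape {(self.L, self.q)}, got {self.fields.shape}"
            )
        if self.gauge_tag not in (GAUGE_FIELDLESS, GAUGE_ZERO_MEAN, GAUGE_OTHER):
            raise ValueError(f"unknown gauge_tag {self.gauge_tag!r}")
        self._index = {c: k for k, c in enumerate(self.alphabet)}

    # -- coupling access ---------------------------------------------------

    def J(self, i: int, j: int) -> np.ndarray:
        """The q×q coupling block for positions (i, j).

        The stored (i<j) block is returned as-is; the (j, i) view is its
        transpose, so ``J(i,j)[a,b] == J(j,i)[b,a]`` always holds.
        """
        if i < j:
            return self.couplings[pair_index(i, j, self.L)]
        return self.couplings[pair_index(j, i, self.L)].T

    def set_J(self, i: int, j: int, block: np.ndarray) -> None:
        block = np.asarray(block, dtype=float)
        if block.shape != (self.q, self.q):
            raise ValueError(f"block must be {(self.q, self.q)}, got {block.shape}")
        if i < j:
            self.couplings[pair_index(i, j, self.L)] = block
        else:
            self.couplings[pair_index(j, i, self.L)] = block.T

    def is_zero_mean(self, atol: float = GAUGE_ATOL) -> bool:
        """True iff every pair's coupling block has zero mean over q×q states."""
        means = self.couplings.mean(axis=(1, 2))
        return bool(np.all(np.abs(means) <= atol))

    def encode(self, symbols: str) -> np.ndarray:
        """Map a symbol string to integer states, naming any offending position."""
        if len(symbols) != self.L:
            raise ValueError(
                f"sequence length {len(symbols)} != model L={self.L}"
            )
        out = np.empty(self.L, dtype=np.intp)
        for k, c in enumerate(symbols):
            try:
                out[k] = self._index[c]
            except KeyError:
                raise ValueError(
                    f"symbol {c!r} at position {k} is not in the model alphabet"
                ) from None
        return out


@dataclass
class AlignedSequence:
    """One sequence aligned to the model's MSA (gaps allowed)."""

    symbols: str
    identifier: str = ""

    def __len__(self) -> int:
        return len(self.symbols)


# ---------------------------------------------------------------------------
# Energy evaluation
# ---------------------------------------------------------------------------

def _pair_arrays(L: int):
    iu, ju = np.triu_indices(L, k=1)
    return iu, ju


def total_energy(model: PottsModel, seq: AlignedSequence | str) -> float:
    """Total Potts statistical energy E(S) = Σ_{i<j} J[i][j][S_i][S_j] + Σ_i h[i][S_i]."""
    symbols = seq.symbols if isinstance(seq, AlignedSequence) else seq
    s = model.encode(symbols)
    iu, ju = _pair_arrays(model.L)
    e_pairs = model.couplings[np.arange(len(iu)), s[iu], s[ju]].sum()
    e_fields = model.fields[np.arange(model.L), s].sum()
    return float(e_pairs + e_fields)


def to_zero_mean_gauge(model: PottsModel) -> tuple[PottsModel, float]:
    """Transform to the zero-mean gauge; the gauge constant is returned separately.

    Each pair block becomes ``J' = J - rowmean - colmean + mean`` (so it averages
    to zero over all q×q state pairs), row/column means are pushed into the
    fields, fields are centred per position, and the total shift is returned as
    a constant: for every sequence,
    ``total_energy(model, S) == total_energy(model', S) + constant``.

    Pairs whose transformed block is all-zero carry no sequence-dependent pair
    energy and can be read as uncoupled.
    """
    q = model.q
    J = model.couplings
    row = J.mean(axis=2, keepdims=True)          # (P, q, 1) mean over b
    col = J.mean(axis=1, keepdims=True)          # (P, 1, q) mean over a
    mean = J.mean(axis=(1, 2), keepdims=True)    # (P, 1, 1)
    J2 = J - row - col + mean

    h2 = model.fields.copy()
    iu, ju = _pair_arrays(model.L)
    # row mean (over b) belongs to position i's field; col mean (over a) to j's
    np.add.at(h2, iu, (row - mean)[:, :, 0])
    np.add.at(h2, ju, (col - mean)[:, 0, :])

    constant = float(mean.sum())
    h_means = h2.mean(axis=1)
    h2 -= h_means[:, None]
    constant += float(h_means.sum())

    out = replace(model, couplings=J2, fields=h2, gauge_tag=GAUGE_ZERO_MEAN)
    return out, constant


# ---------------------------------------------------------------------------
# MCMC sampling
# ---------------------------------------------------------------------------

def _dense_couplings(model: PottsModel) -> np.ndarray:
    """Full (L, L, q, q) coupling tensor with W[i,j] = J(i,j); diagonal zero."""
    L, q = model.L, model.q
    W = np.zeros((L, L, q, q))
    iu, ju = _pair_arrays(L)
    W[iu, ju] = model.couplings
    W[ju, iu] = np.transpose(model.couplings, (0, 2, 1))
    return W


def sample_sequences(
    model: PottsModel,
    n: int,
    seed: int,
    burn_in: int | None = None,
    thinning: int | None = None,
    n_chains: int = 64,
) -> list[AlignedSequence]:
    """Draw ``n`` sequences from P(S) ∝ exp(-E(S)) by single-site Metropolis.

    The proposal resamples one uniformly chosen site to a uniform random state;
    acceptance probability is ``min(1, exp(-ΔE))``.  ``n_chains`` independent
    chains are advanced in lockstep (each burnt in for ``burn_in`` sweeps of
    single-site updates, then thinned every ``thinning`` updates); defaults are
    ``burn_in = 1000·L`` and ``thinning = 10·L`` elementary updates.  Identical
    arguments reproduce the identical sample.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    burn_in = 1000 * model.L if burn_in is None else burn_in
    thinning = 10 * model.L if thinning is None else thinning
    if burn_in <= 0 or thinning <= 0:
        raise ValueError("burn_in and thinning must be positive")
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")

    rng = np.random.default_rng(seed)
    L, q = model.L, model.q
    W = _dense_couplings(model)  # (L, L, q, q)
    h = model.fields

    C = min(n_chains, n)
    per_chain = -(-n // C)  # ceil
    state = rng.integers(0, q, size=(C, L))
    chains = np.arange(C)

    samples: list[np.ndarray] = []
    total_steps = burn_in + per_chain * thinning
    for step in range(total_steps):
        site = int(rng.integers(L))
        prop = rng.integers(0, q, size=C)
        cur = state[:, site]
        # ΔE = h(new) - h(old) + Σ_{j != site} [J(site,j,new,s_j) - J(site,j,old,s_j)]
        Wsite = W[site]  # (L, q, q)
        e_new = h[site, prop] + Wsite[np.arange(L)[:, None], prop[None, :],
                                      state.T].sum(axis=0)
        e_old = h[site, cur] + Wsite[np.arange(L)[:, None], cur[None, :],
                                     state.T].sum(axis=0)
        dE = e_new - e_old
        accept = rng.random(C) < np.exp(np.minimum(-dE, 0.0))
        state[chains[accept], site] = prop[accept]
        if step >= burn_in and (step - burn_in + 1) % thinning == 0:
            samples.append(state.copy())

    flat = np.concatenate(samples, axis=0)[:n]
    alpha = np.array(list(model.alphabet))
    return [
        AlignedSequence("".join(alpha[row]), identifier=f"sample_{k}")
        for k, row in enumerate(flat)
    ]


# ---------------------------------------------------------------------------
# I/O: sequences (FASTA / Stockholm via Biopython) and model containers
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[AlignedSequence]:
    from Bio import SeqIO

    return [
        AlignedSequence(str(rec.seq).upper(), identifier=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path, sequences: list[AlignedSequence]) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f">{s.identifier or 'seq'}\n{s.symbols}\n")


def read_stockholm(path) -> list[AlignedSequence]:
    from Bio import AlignIO

    aln = AlignIO.read(str(path), "stockholm")
    return [AlignedSequence(str(rec.seq).upper(), identifier=rec.id) for rec in aln]


def write_stockholm(path, sequences: list[AlignedSequence]) -> None:
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import AlignIO

    aln = MultipleSeqAlignment(
        [SeqRecord(Seq(s.symbols), id=s.identifier or f"seq{k}", description="")
         for k, s in enumerate(sequences)]
    )
    AlignIO.write(aln, str(path), "stockholm")


def save_model(path, model: PottsModel) -> None:
    """Save as an .npz tensor container with a JSON metadata block."""
    meta = json.dumps(
        {"L": model.L, "q": model.q, "alphabet": model.alphabet,
         "gauge_tag": model.gauge_tag}
    )
    np.savez(path, couplings=model.couplings, fields=model.fields,
             meta=np.frombuffer(meta.encode(), dtype=np.uint8))


def load_model(path) -> PottsModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        return PottsModel(
            L=meta["L"], q=meta["q"], alphabet=meta["alphabet"],
            couplings=z["couplings"], fields=z["fields"],
            gauge_tag=meta["gauge_tag"],
        )


def write_couplings_text(path_or_fh, model: PottsModel) -> None:
    """Plain-text exchange format: header lines then one (i, j, a, b, J) per line.

    Only non-zero couplings of the i<j triangle are written; fields follow as
    (i, a, h) lines prefixed with 'h'.  Indices are 0-based columns, symbols
    are alphabet letters.
    """
    own = isinstance(path_or_fh, (str, bytes)) or hasattr(path_or_fh, "__fspath__")
    fh = open(path_or_fh, "w") if own else path_or_fh
    try:
        fh.write(f"# potts L={model.L} q={model.q} alphabet={model.alphabet} "
                 f"gauge={model.gauge_tag}\n")
        iu, ju = _pair_arrays(model.L)
        for p in range(len(iu)):
            blk = model.couplings[p]
            for a, b in zip(*np.nonzero(blk)):
                fh.write(f"J\t{iu[p]}\t{ju[p]}\t{model.alphabet[a]}\t"
                         f"{model.alphabet[b]}\t{float(blk[a, b])!r}\n")
        for i, a in zip(*np.nonzero(model.fields)):
            fh.write(f"h\t{i}\t{model.alphabet[a]}\t{float(model.fields[i, a])!r}\n")
    finally:
        if own:
            fh.close()


def read_couplings_text(path_or_fh) -> PottsModel:
    own = isinstance(path_or_fh, (str, bytes)) or hasattr(path_or_fh, "__fspath__")
    fh = open(path_or_fh) if own else path_or_fh
    try:
        header = fh.readline().strip()
        if not header.startswith("# potts"):
            raise ValueError("not a Potts text exchange file (missing '# potts' header)")
        kv = dict(tok.split("=", 1) for tok in header[2:].split()[1:])
        model = PottsModel(L=int(kv["L"]), q=int(kv["q"]), alphabet=kv["alphabet"],
                           gauge_tag=kv.get("gauge", GAUGE_OTHER))
        idx = model._index
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            if parts[0] == "J":
                i, j = int(parts[1]), int(parts[2])
                a, b = idx[parts[3]], idx[parts[4]]
                model.couplings[pair_index(i, j, model.L), a, b] = float(parts[5])
            elif parts[0] == "h":
                model.fields[int(parts[1]), idx[parts[2]]] = float(parts[3])
            else:
                raise ValueError(f"unrecognised record {parts[0]!r}")
        return model
    finally:
        if own:
            fh.close()
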