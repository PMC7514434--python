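"""Potts model representation, toy-model generation, energies, gauge and scores.

A Potts model assigns to every length-``L`` sequence ``A`` over a ``q``-letter
alphabet the energy

    H(A) = - sum_{i<j} J_ij(A_i, A_j) - sum_i h_i(A_i)

and the probability ``P(A) = exp(-H(A)) / Z``.  Couplings are stored once per
unordered pair ``i < j``; the accessor :meth:`PottsModel.get_J` handles the
symmetric convention ``J_ij(a, b) = J_ji(b, a)``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Alphabet",
    "TOY_ALPHABET",
    "PROTEIN_ALPHABET",
    "PottsModel",
    "ToyModelParams",
    "MutantTable",
    "pair_index",
    "n_pairs",
    "hamiltonian",
    "generate_toy_model",
    "mutational_effects",
    "zero_sum_gauge",
    "coupling_scores",
    "write_model",
    "read_model",
]


@dataclass(frozen=True)
class Alphabet:
    """Bijection between symbols and the integer states ``0..q-1``."""

    symbols: str

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise ValueError("alphabet needs at least 2 symbols")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")

    @property
    def q(self) -> int:
        return len(self.symbols)

    def encode(self, seq: str) -> np.ndarray:
        try:
            return np.array([self.symbols.index(s) for s in seq], dtype=np.int8)
        except ValueError as exc:
            raise ValueError(f"symbol not in alphabet {self.symbols!r}: {exc}") from exc

    def decode(self, states) -> str:
        return "".join(self.symbols[int(a)] for a in states)


#: 4-state alphabet used by the toy model.
TOY_ALPHABET = Alphabet("ACGT")
#: 20 amino acids plus the alignment gap (q = 21).
PROTEIN_ALPHABET = Alphabet("-ACDEFGHIKLMNPQRSTVWY")


def n_pairs(L: int) -> int:
    return L * (L - 1) // 2


def pair_index(i: int, j: int, L: int) -> int:
    """Index of unordered pair (i, j), i < j, in lexicographic order."""
    if not 0 <= i < j < L:
        raise ValueError(f"need 0 <= i < j < L, got i={i}, j={j}, L={L}")
    return i * L - i * (i + 1) // 2 + (j - i - 1)


class PottsModel:
    """Pairwise Potts model with fields ``h`` (L, q) and couplings ``J``.

    Parameters
    ----------
    L, q
        Number of sites and alphabet size.
    h
        Field array of shape (L, q); zeros if omitted.
    J
        Coupling array of shape (L*(L-1)/2, q, q), one q x q table per
        unordered pair i < j in lexicographic order; zeros if omitted.
    """

    def __init__(self, L: int, q: int, h=None, J=None, alphabet: Alphabet | None = None):
        if L < 1 or q < 2:
            raise ValueError("need L >= 1 and q >= 2")
        self.L = int(L)
        self.q = int(q)
        self.h = np.zeros((L, q)) if h is None else np.asarray(h, dtype=float)
        self.J = np.zeros((n_pairs(L), q, q)) if J is None else np.asarray(J, dtype=float)
        if self.h.shape != (L, q):
            raise ValueError(f"h must have shape {(L, q)}, got {self.h.shape}")
        if self.J.shape != (n_pairs(L), q, q):
            raise ValueError(f"J must have shape {(n_pairs(L), q, q)}, got {self.J.shape}")
        if not (np.isfinite(self.h).all() and np.isfinite(self.J).all()):
            raise ValueError("model parameters must be finite")
        self.alphabet = alphabet

    def get_J(self, i: int, j: int) -> np.ndarray:
        """Coupling table J_ij(a, b); the transpose is returned when i > j."""
        if i == j:
            raise ValueError("no self-coupling J_ii")
        if i < j:
            return self.J[pair_index(i, j, self.L)]
        return self.J[pair_index(j, i, self.L)].T

    def set_J(self, i: int, j: int, table) -> None:
        table = np.asarray(table, dtype=float)
        if i < j:
            self.J[pair_index(i, j, self.L)] = table
        else:
            self.J[pair_index(j, i, self.L)] = table.T

    def coupling_tensor(self) -> np.ndarray:
        """Dense symmetric tensor Jf[i, j, a, b] with zero diagonal blocks.

        Convenience layout for the sampling / energy kernels; Jf[i, j] is the
        table of pair (i, j) oriented so the first state index belongs to i.
        """
        L, q = self.L, self.q
        Jf = np.zeros((L, L, q, q))
        k = 0
        for i in range(L):
            for j in range(i + 1, L):
                Jf[i, j] = self.J[k]
                Jf[j, i] = self.J[k].T
                k += 1
        return Jf

    def copy(self) -> "PottsModel":
        return PottsModel(self.L, self.q, self.h.copy(), self.J.copy(), self.alphabet)

    def scaled(self, factor: float) -> "PottsModel":
        return PottsModel(self.L, self.q, factor * self.h, factor * self.J, self.alphabet)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PottsModel)
            and self.L == other.L
            and self.q == other.q
            and np.array_equal(self.h, other.h)
            and np.array_equal(self.J, other.J)
        )


@dataclass(frozen=True)
class ToyModelParams:
    """Parameters of the sparse, predominantly ferromagnetic toy model.

    Defaults are the frozen toy preset: L=25, q=4, mean degree c=3,
    couplings s_ij * x_ij * delta_ab with x ~ N(0.8, 0.2), fields ~ N(0, 0.6).
    ``field_mode`` controls whether each field entry h_i(a) is drawn i.i.d.
    ("per_state", default) or one draw is shared across a site ("per_site").
    """

    L: int = 25
    q: int = 4
    c: float = 3.0
    mu_J: float = 0.8
    sigma_J: float = 0.2
    mu_h: float = 0.0
    sigma_h: float = 0.6
    seed: int = 0
    field_mode: str = "per_state"

    def __post_init__(self) -> None:
        if not 0.0 <= self.c / self.L <= 1.0:
            raise ValueError("c/L must lie in [0, 1]")
        if self.sigma_J < 0 or self.sigma_h < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.field_mode not in ("per_state", "per_site"):
            raise ValueError("field_mode must be 'per_state' or 'per_site'")


@dataclass
class MutantTable:
    """Energy shifts of all L*(q-1) single mutants of a wild-type sequence."""

    wild_type: np.ndarray
    sites: np.ndarray  # (n,) mutated position
    states: np.ndarray  # (n,) new state at that position
    delta_H: np.ndarray  # (n,) H(mutant) - H(wild type)

    def __len__(self) -> int:
        return len(self.delta_H)


def _check_seq(model: PottsModel, seq) -> np.ndarray:
    seq = np.asarray(seq)
    if seq.ndim != 1 or seq.shape[0] != model.L:
        raise ValueError(f"sequence must have length {model.L}, got shape {seq.shape}")
    if seq.min() < 0 or seq.max() >= model.q:
        raise ValueError(f"sequence states must lie in [0, {model.q})")
    return seq.astype(np.int64)


def hamiltonian(model: PottsModel, seq) -> float:
    """Energy H(A) = -sum_{i<j} J_ij(A_i, A_j) - sum_i h_i(A_i)."""
    s = _check_seq(model, seq)
    L = model.L
    e = float(model.h[np.arange(L), s].sum())
    iu, ju = np.triu_indices(L, k=1)
    e += float(model.J[np.arange(len(iu)), s[iu], s[ju]].sum())
    return -e


def hamiltonian_batch(model: PottsModel, seqs: np.ndarray) -> np.ndarray:
    """Vectorized :func:`hamiltonian` over rows of an (M, L) array."""
    seqs = np.asarray(seqs, dtype=np.int64)
    M, L = seqs.shape
    if L != model.L:
        raise ValueError("sequence length mismatch")
    e = model.h[np.arange(L)[None, :], seqs].sum(axis=1)
    iu, ju = np.triu_indices(L, k=1)
    e += model.J[np.arange(len(iu))[None, :], seqs[:, iu], seqs[:, ju]].sum(axis=1)
    return -e


def generate_toy_model(params: ToyModelParams) -> tuple[PottsModel, list[tuple[int, int]]]:
    """Draw a sparse random toy model; returns (model, true contact edges).

    Edge indicators s_ij ~ Bernoulli(c/L); on present edges the coupling is
    x * identity with x ~ N(mu_J, sigma_J); fields are N(mu_h, sigma_h).
    Same seed -> identical model.
    """
    rng = np.random.default_rng(params.seed)
    L, q = params.L, params.q
    s = rng.random(n_pairs(L)) < params.c / L
    x = rng.normal(params.mu_J, params.sigma_J, size=n_pairs(L))
    J = np.zeros((n_pairs(L), q, q))
    J[s] = x[s, None, None] * np.eye(q)[None]
    if params.field_mode == "per_state":
        h = rng.normal(params.mu_h, params.sigma_h, size=(L, q))
    else:
        h = np.repeat(rng.normal(params.mu_h, params.sigma_h, size=(L, 1)), q, axis=1)
    edges = []
    k = 0
    for i in range(L):
        for j in range(i + 1, L):
            if s[k]:
                edges.append((i, j))
            k += 1
    alphabet = TOY_ALPHABET if q == 4 else None
    return PottsModel(L, q, h, J, alphabet), edges


def mutational_effects(model: PottsModel, wt) -> MutantTable:
    """Energy shift of every single-state substitution of the wild type.

    delta_H(i, a) = H(A^(i,a)) - H(A) is computed incrementally: only the
    field of site i and the couplings touching i change under the flip.
    """
    s = _check_seq(model, wt)
    L, q = model.L, model.q
    Jf = model.coupling_tensor()
    # local field of site i given the rest: g[i, a] = h_i(a) + sum_{j != i} J_ij(a, A_j)
    g = model.h + Jf[np.arange(L)[:, None], np.arange(L)[None, :], :, s[None, :]].sum(axis=1)
    sites, states, deltas = [], [], []
    for i in range(L):
        for a in range(q):
            if a == int(s[i]):
                continue
            sites.append(i)
            states.append(a)
            deltas.append(g[i, s[i]] - g[i, a])
    return MutantTable(
        wild_type=s.copy(),
        sites=np.array(sites, dtype=np.int64),
        states=np.array(states, dtype=np.int64),
        delta_H=np.array(deltas, dtype=float),
    )


def zero_sum_gauge(model: PottsModel) -> PottsModel:
    """Gauge-equivalent model whose coupling tables have zero row/column sums.

    The removed row/column means are pushed into the fields so that energies
    shift only by a sequence-independent constant.
    """
    L, q = model.L, model.q
    J = model.J
    row = J.mean(axis=2, keepdims=True)  # mean over b -> per (pair, a)
    col = J.mean(axis=1, keepdims=True)  # mean over a -> per (pair, b)
    tot = J.mean(axis=(1, 2), keepdims=True)
    Jp = J - row - col + tot
    h = model.h.copy()
    k = 0
    for i in range(L):
        for j in range(i + 1, L):
            h[i] += row[k, :, 0] - tot[k, 0, 0]
            h[j] += col[k, 0, :] - tot[k, 0, 0]
            k += 1
    h -= h.mean(axis=1, keepdims=True)
    return PottsModel(L, q, h, Jp, model.alphabet)


def coupling_scores(model: PottsModel, apc: bool = False) -> np.ndarray:
    """Symmetric L x L matrix of Frobenius norms of zero-sum-gauge couplings.

    The diagonal is NaN (ignore marker).  Average-product correction is
    available behind ``apc`` but off by default.
    """
    zs = zero_sum_gauge(model)
    L = model.L
    F = np.zeros((L, L))
    k = 0
    for i in range(L):
        for j in range(i + 1, L):
            F[i, j] = F[j, i] = np.sqrt((zs.J[k] ** 2).sum())
            k += 1
    if apc:
        off = ~np.eye(L, dtype=bool)
        mrow = F.sum(axis=1) / (L - 1)
        mall = F[off].mean()
        F = F - np.outer(mrow, mrow) / mall
        F[~off] = 0.0
        F = np.maximum(F, F.T) * 0 + (F + F.T) / 2.0
    np.fill_diagonal(F, np.nan)
    return F


# ---------------------------------------------------------------------------
# plain-text serialization


def write_model(model: PottsModel, path_or_file) -> None:
    """Plain-text model dump: header then "J i j a b value" / "h i a value".

    Indices are 1-based; states are written as alphabet letters when an
    alphabet is attached, else as integers.
    """
    alph = model.alphabet

    def sym(a: int) -> str:
        return alph.symbols[a] if alph is not None else str(a)

    buf = io.StringIO()
    buf.write(f"L {model.L}\nq {model.q}\n")
    if alph is not None:
        buf.write(f"alphabet {alph.symbols}\n")
    k = 0
    for i in range(model.L):
        for j in range(i + 1, model.L):
            for a in range(model.q):
                for b in range(model.q):
                    v = model.J[k, a, b]
                    if v != 0.0:
                        buf.write(f"J {i + 1} {j + 1} {sym(a)} {sym(b)} {float(v)!r}\n")
            k += 1
    for i in range(model.L):
        for a in range(model.q):
            v = model.h[i, a]
            if v != 0.0:
                buf.write(f"h {i + 1} {sym(a)} {float(v)!r}\n")
    if hasattr(path_or_file, "write"):
        path_or_file.write(buf.getvalue())
    else:
        with open(path_or_file, "w") as fh:
            fh.write(buf.getvalue())


def read_model(path_or_file) -> PottsModel:
    """Read the plain-text format of :func:`write_model`; missing entries are 0."""
    if hasattr(path_or_file, "read"):
        text = path_or_file.read()
    else:
        with open(path_or_file) as fh:
            text = fh.read()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    header: dict[str, str] = {}
    body = []
    for ln in lines:
        key = ln.split()[0]
        if key in ("L", "q", "alphabet"):
            header[key] = ln.split(maxsplit=1)[1]
        else:
            body.append(ln)
    if "L" not in header or "q" not in header:
        raise ValueError("model file must declare L and q")
    L, q = int(header["L"]), int(header["q"])
    alph = Alphabet(header["alphabet"]) if "alphabet" in header else None

    def state(tok: str) -> int:
        if alph is not None and tok in alph.symbols:
            return alph.symbols.index(tok)
        return int(tok)

    model = PottsModel(L, q, alphabet=alph)
    for ln in body:
        parts = ln.split()
        if parts[0] == "J":
            i, j = int(parts[1]) - 1, int(parts[2]) - 1
            a, b = state(parts[3]), state(parts[4])
            if i < j:
                model.J[pair_index(i, j, L), a, b] = float(parts[5])
            else:
                model.J[pair_index(j, i, L), b, a] = float(parts[5])
        elif parts[0] == "h":
            model.h[int(parts[1]) - 1, state(parts[2])] = float(parts[3])
        else:
            raise ValueError(f"unrecognized model line: {ln!r}")
    return model
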