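"""k-mer community profiles: length-normalized, log-transformed and
z-standardized k-mer counts compared by Pearson correlation.

Counts slide by 1; windows containing N contribute nothing.  Counts plus
a pseudocount are normalized per kilobase of counted windows and
log2-transformed; standardization uses the per-k-mer mean and population
standard deviation across a designated reference sequence set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
SD_FLOOR = 1e-8


def kmer_order(k: int) -> list[str]:
    """Lexicographic list of all 4^k words over ACGT."""
    return ["".join(p) for p in product("ACGT", repeat=k)]


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), -1, dtype=np.int64)
    for base, code in _BASE_CODE.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return codes


def count_kmers(seq: str, k: int) -> np.ndarray:
    """Count k-mer occurrences; returns a vector of length 4^k.

    Any window containing a non-ACGT character (N) is skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    codes = _encode(seq.upper())
    n_windows = len(seq) - k + 1
    # rolling polynomial code over base-4 digits; invalid windows masked out
    window_codes = np.zeros(n_windows, dtype=np.int64)
    valid = np.ones(n_windows, dtype=bool)
    for j in range(k):
        digit = codes[j:j + n_windows]
        valid &= digit >= 0
        window_codes = window_codes * 4 + np.where(digit >= 0, digit, 0)
    counts = np.bincount(window_codes[valid], minlength=4 ** k)
    return counts.astype(np.int64)


def _log_norm(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    """log2 of per-kilobase-normalized counts plus a pseudocount.

    The pseudocount is added after normalization so that the profile is
    exactly invariant to sequence duplication (length cancels).
    """
    counted = counts.sum()
    if counted == 0:
        raise ValueError("no countable windows (all contain N)")
    return np.log2(counts / (counted / 1000.0) + pseudocount)


@dataclass
class KmerReference:
    k: int
    kmer_order: list[str]
    mean: np.ndarray
    sd: np.ndarray
    pseudocount: float
    member_z: np.ndarray  # reference members' z-profiles, shape (n_refs, 4^k)
    member_ids: list[str]

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if (self.sd <= 0).any():
            raise ValueError("reference sd must be positive everywhere")


@dataclass
class KmerProfile:
    seq_id: str
    z: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.z).all():
            raise ValueError(f"non-finite z-profile for {self.seq_id!r}")


def build_kmer_reference(
    ref_seqs: list[tuple[str, str]] | list,
    k: int = 4,
    pseudocount: float = 1.0,
) -> KmerReference:
    """Estimate per-k-mer mean/sd from a functional reference sequence set.

    ``ref_seqs`` is a list of (id, sequence) pairs or objects with
    ``id``/``seq`` attributes.  Requires at least 2 sequences (population
    sd is undefined otherwise) and a positive pseudocount.
    """
    pairs = [(s.id, s.seq) if hasattr(s, "seq") else (s[0], s[1]) for s in ref_seqs]
    if len(pairs) < 2:
        raise ValueError("need >= 2 reference sequences to estimate sd")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if k < 2:
        raise ValueError("k must be >= 2")
    logn = np.stack([_log_norm(count_kmers(seq, k), pseudocount) for _, seq in pairs])
    mean = logn.mean(axis=0)
    sd = np.maximum(logn.std(axis=0, ddof=0), SD_FLOOR)
    member_z = (logn - mean) / sd
    return KmerReference(k, kmer_order(k), mean, sd, pseudocount,
                         member_z, [i for i, _ in pairs])


def kmer_profile(seq: str, reference: KmerReference, seq_id: str = "") -> KmerProfile:
    """Standardized log length-normalized k-mer profile of ``seq``."""
    logn = _log_norm(count_kmers(seq, reference.k), reference.pseudocount)
    return KmerProfile(seq_id, (logn - reference.mean) / reference.sd)


def kmer_similarity(p: KmerProfile | np.ndarray, q: KmerProfile | np.ndarray) -> float:
    """Pearson correlation between two profiles; NaN if either has zero variance."""
    x = p.z if isinstance(p, KmerProfile) else np.asarray(p, dtype=float)
    y = q.z if isinstance(q, KmerProfile) else np.asarray(q, dtype=float)
    if len(x) != len(y):
        raise ValueError("profiles have different lengths (different references?)")
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle (Altschul-Erickson Euler walk).

    Preserves the exact dinucleotide composition of ``seq``.  N and other
    non-ACGT characters are treated as ordinary vertices, so N-adjacency
    is preserved too.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    n_edges = len(seq) - 1
    for a, b in zip(seq[:-1], seq[1:]):
        edges.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]

    # Altschul-Erickson: a random edge ordering yields an Euler walk iff
    # the last-exit edge of every vertex except the terminal one forms a
    # spanning arborescence toward the terminal vertex.  Sample last-exit
    # edges until that holds (cheap: at most 5 vertices for ACGTN).
    non_terminal = [v for v in edges if v != last]
    last_exit: dict[str, int] = {}
    for _attempt in range(100000):
        last_exit = {v: int(rng.integers(len(edges[v]))) for v in non_terminal}
        ok = True
        for v in non_terminal:
            cur, seen = v, {v}
            while cur != last:
                cur = edges[cur][last_exit[cur]]
                if cur in seen or (cur != last and cur not in last_exit):
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - disconnected edge graph
        return seq

    order: dict[str, list[str]] = {}
    for v, targets in edges.items():
        idx = list(range(len(targets)))
        held = last_exit.get(v)
        if held is not None:
            idx.remove(held)
        perm = [idx[i] for i in rng.permutation(len(idx))]
        if held is not None:
            perm.append(held)
        order[v] = [targets[i] for i in perm]

    out = [first]
    pos = {v: 0 for v in order}
    cur = first
    for _ in range(n_edges):
        nxt = order[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)
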