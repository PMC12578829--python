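"""Repeat-insertion-domain calling on lncRNA transcripts.

Per transcript: (1) local alignment against every consensus in the TE
library; (2) hits overlapping by more than half of the shorter hit are
merged, keeping the best-scoring one; (3) fragments mostly (>= 80%)
covered by a low-complexity interval are reclassified as poly-base
artefacts; (4) surviving fragments are annotated with a k-mer community
delta: similarity of the fragment profile to the functional reference
minus the mean similarity of dinucleotide-preserving shuffles of the
fragment.  The delta is reported as evidence, not used as a hard filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from selnc.ridl_seekrp.align import AlignmentHit, ScoringScheme, local_align
from selnc.ridl_seekrp.kmer import (
    KmerReference,
    dinucleotide_shuffle,
    kmer_profile,
    kmer_similarity,
)
from selnc.ridl_seekrp.lowcomplexity import detect_low_complexity

KLASSES = ("TE_repeat", "low_complexity", "none")
STATUSES = ("valid_RIDL", "polyA_only", "no_RIDL")


@dataclass(frozen=True)
class RIDLParams:
    n_shuffles: int = 20
    shuffle_seed: int = 0
    merge_overlap_frac: float = 0.5
    low_complexity_cover: float = 0.8
    min_run: int = 15
    min_purity: float = 0.9


@dataclass
class RIDLCall:
    seq_id: str
    klass: str
    fragment: tuple[int, int] | None = None
    family: str | None = None
    hit: AlignmentHit | None = None
    kmer_delta: float | None = None

    def __post_init__(self) -> None:
        if self.klass not in KLASSES:
            raise ValueError(f"unknown klass {self.klass!r}")
        if self.klass == "TE_repeat" and (self.hit is None or self.family is None):
            raise ValueError("TE_repeat calls require an alignment hit and family")
        if self.klass == "none" and self.fragment is not None:
            raise ValueError("klass=none calls carry no fragment")


def _merge_fragments(hits: list[AlignmentHit], overlap_frac: float) -> list[AlignmentHit]:
    """Collapse hits whose query intervals overlap > overlap_frac of the
    shorter one, keeping the best-scoring hit of each cluster."""
    remaining = sorted(hits, key=lambda h: -h.score)
    kept: list[AlignmentHit] = []
    for hit in remaining:
        absorbed = False
        for other in kept:
            ov = min(hit.q_end, other.q_end) - max(hit.q_start, other.q_start)
            if ov > overlap_frac * min(hit.q_length, other.q_length):
                absorbed = True
                break
        if not absorbed:
            kept.append(hit)
    kept.sort(key=lambda h: h.q_start)
    return kept


def _reference_similarity(z_profile, reference: KmerReference) -> float:
    """Mean Pearson similarity of a profile to the reference members."""
    sims = [kmer_similarity(z_profile, member) for member in reference.member_z]
    return float(np.nanmean(sims))


def _kmer_delta(
    fragment_seq: str,
    reference: KmerReference,
    params: RIDLParams,
    rng: np.random.Generator,
) -> float | None:
    if len(fragment_seq) < reference.k:
        return None
    try:
        frag_z = kmer_profile(fragment_seq, reference).z
    except ValueError:
        return None
    observed = _reference_similarity(frag_z, reference)
    null_sims = []
    for _ in range(params.n_shuffles):
        shuffled = dinucleotide_shuffle(fragment_seq, rng)
        try:
            null_z = kmer_profile(shuffled, reference).z
        except ValueError:
            continue
        null_sims.append(_reference_similarity(null_z, reference))
    if not null_sims:
        return None
    return observed - float(np.mean(null_sims))


def call_ridls(
    transcript,
    te_library,
    kmer_reference: KmerReference | None = None,
    scheme: ScoringScheme = ScoringScheme(),
    params: RIDLParams = RIDLParams(),
) -> list[RIDLCall]:
    """Run the full RIDL detection cascade on one transcript.

    ``transcript`` and the ``te_library`` entries are objects with
    ``id``/``seq`` attributes (e.g. :class:`selnc.formats_io.SequenceRecord`).
    """
    if not te_library:
        raise ValueError("TE consensus library is empty")
    seq_id, seq = transcript.id, transcript.seq

    hits: list[AlignmentHit] = []
    for consensus in te_library:
        hits.extend(
            local_align(seq, consensus.seq, scheme,
                        query_id=seq_id, target_id=consensus.id)
        )
    fragments = _merge_fragments(hits, params.merge_overlap_frac)
    if not fragments:
        return [RIDLCall(seq_id, "none")]

    lc_intervals = detect_low_complexity(seq, params.min_run, params.min_purity)
    rng = np.random.default_rng(params.shuffle_seed)
    calls: list[RIDLCall] = []
    for hit in fragments:
        frag = (hit.q_start, hit.q_end)
        covered = 0
        for s, e, _base in lc_intervals:
            covered += max(0, min(e, frag[1]) - max(s, frag[0]))
        if covered >= params.low_complexity_cover * (frag[1] - frag[0]):
            span = seq[frag[0]:frag[1]]
            dom = max("ACGT", key=span.count)
            calls.append(
                RIDLCall(seq_id, "low_complexity", fragment=frag,
                         family="polyA" if dom == "A" else f"poly{dom}", hit=hit)
            )
            continue
        delta = None
        if kmer_reference is not None:
            delta = _kmer_delta(seq[frag[0]:frag[1]], kmer_reference, params, rng)
        calls.append(
            RIDLCall(seq_id, "TE_repeat", fragment=frag, family=hit.target_id,
                     hit=hit, kmer_delta=delta)
        )
    return calls


def classify_se_lncrna(calls: list[RIDLCall]) -> str:
    """Triage a transcript's calls: valid_RIDL / polyA_only / no_RIDL."""
    if not calls:
        raise ValueError("empty call list")
    ids = {c.seq_id for c in calls}
    if len(ids) != 1:
        raise ValueError(f"calls span multiple transcripts: {sorted(ids)}")
    klasses = {c.klass for c in calls}
    if "TE_repeat" in klasses:
        return "valid_RIDL"
    if "low_complexity" in klasses:
        return "polyA_only"
    return "no_RIDL"
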