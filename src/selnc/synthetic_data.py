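"""Synthetic inputs with planted ground truth for every pipeline stage.

Generates SE intervals with a planted fraction of overlapping lncRNA
genes, transcript sequences with planted mutated TE-consensus insertions
and poly(A) runs, an expression matrix with subtype-specific shifts, and
survival times whose hazard is driven by planted prognostic features.
Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from selnc.formats_io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    SequenceRecord,
    write_bed,
    write_clinical,
    write_fasta,
    write_gtf,
    write_matrix,
)

SUBTYPE_VOCAB = ("Basal", "Her2", "LumA", "LumB", "Normal")
_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class GenomeConfig:
    n_chroms: int = 2
    chrom_len: int = 1_000_000
    n_se: int = 50
    se_len_range: tuple[int, int] = (2000, 10000)
    n_genes: int = 100
    gene_len_range: tuple[int, int] = (1000, 5000)
    se_overlap_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.se_overlap_fraction <= 1.0):
            raise ValueError("se_overlap_fraction must lie in [0, 1]")


@dataclass
class SequenceConfig:
    transcript_len: int = 1000
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    te_len_range: tuple[int, int] = (150, 300)
    substitution_rate: float = 0.05
    indel_rate: float = 0.0
    polya_len: int = 60
    class_fractions: tuple[float, float, float] = (0.3, 0.3, 0.4)  # TE, polyA, none
    n_functional_ref: int = 10
    functional_ref_len: int = 2000

    def __post_init__(self) -> None:
        if not (0.0 <= self.substitution_rate <= 0.3):
            raise ValueError("substitution_rate must lie in [0, 0.3]")
        if not (0.0 <= self.indel_rate <= 0.3):
            raise ValueError("indel_rate must lie in [0, 0.3]")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")


@dataclass
class ExpressionConfig:
    subtypes: tuple[str, ...] = SUBTYPE_VOCAB
    n_per_subtype: int = 40
    baseline_mean: float = 6.0
    baseline_sd: float = 1.0
    shift: float = 2.0
    noise_sd: float = 0.5
    n_de_per_subtype: int = 10
    target_subtype: str = "Basal"


@dataclass
class SurvivalConfig:
    n_prognostic: int = 5
    beta: float = 1.0
    baseline_hazard: float = 0.1
    censoring_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.censoring_fraction <= 0.9):
            raise ValueError("censoring_fraction must lie in [0, 0.9]")


@dataclass
class SimConfig:
    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    sequence: SequenceConfig = field(default_factory=SequenceConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    planted_hit: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        def tupled(cfg_cls, sub):
            kwargs = dict(sub or {})
            for key, val in kwargs.items():
                if isinstance(val, list):
                    kwargs[key] = tuple(val)
            return cfg_cls(**kwargs)
        return cls(
            seed=int(d.get("seed", 0)),
            genome=tupled(GenomeConfig, d.get("genome")),
            sequence=tupled(SequenceConfig, d.get("sequence")),
            expression=tupled(ExpressionConfig, d.get("expression")),
            survival=tupled(SurvivalConfig, d.get("survival")),
            planted_hit=bool(d.get("planted_hit", True)),
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    se_lncrna_ids: set[str] = field(default_factory=set)
    se_pairs: list[tuple[str, str]] = field(default_factory=list)
    ridl_class: dict[str, str] = field(default_factory=dict)
    ridl_coords: dict[str, tuple[int, int]] = field(default_factory=dict)
    de_features: dict[str, set[str]] = field(default_factory=dict)
    prognostic_beta: dict[str, float] = field(default_factory=dict)
    linear_predictor: np.ndarray | None = None
    hit_gene: str | None = None


@dataclass
class SimBundle:
    config: SimConfig
    se_intervals: list[GenomicInterval]
    gene_models: list[GeneModel]
    transcripts: list[SequenceRecord]
    te_library: list[SequenceRecord]
    functional_ref: list[SequenceRecord]
    expression: ExpressionMatrix
    clinical: ClinicalTable
    centroids: pd.DataFrame
    truth: SimTruth


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------

def random_sequence(length: int, rng: np.random.Generator,
                    composition=(0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(rng.choice(_BASES, size=length, p=np.asarray(composition)))


def mutate_sequence(seq: str, sub_rate: float, indel_rate: float,
                    rng: np.random.Generator) -> tuple[str, int]:
    """Apply substitutions and short indels; returns (mutated, n_subs)."""
    out = []
    n_subs = 0
    for base in seq:
        r = rng.random()
        if indel_rate > 0 and r < indel_rate / 2:
            continue  # deletion
        if indel_rate > 0 and r < indel_rate:
            out.append(base)
            out.append(str(rng.choice(_BASES)))  # insertion after
            continue
        if rng.random() < sub_rate:
            alternatives = [b for b in "ACGT" if b != base]
            out.append(alternatives[rng.integers(3)])
            n_subs += 1
        else:
            out.append(base)
    return "".join(out), n_subs


def make_te_library(seed: int = 777) -> list[SequenceRecord]:
    """Fixed synthetic consensus library: a 300-nt L2-like element and an
    A-rich low-complexity consensus.  No licensed repeat content."""
    rng = np.random.default_rng(seed)
    l2_like = random_sequence(300, rng, (0.3, 0.2, 0.2, 0.3))
    a_rich = "".join(
        "A" if rng.random() < 0.95 else str(rng.choice(_BASES))
        for _ in range(120)
    )
    return [SequenceRecord("L2_like_sim", l2_like),
            SequenceRecord("polyA_rich_sim", a_rich)]


# ---------------------------------------------------------------------------
# Stage generators
# ---------------------------------------------------------------------------

def simulate_annotation(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[GenomicInterval], list[GeneModel], SimTruth]:
    """SE intervals plus gene models with an exact planted overlap set."""
    g = config.genome
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ses: list[GenomicInterval] = []
    for i in range(g.n_se):
        chrom = f"chr{rng.integers(1, g.n_chroms + 1)}"
        length = int(rng.integers(g.se_len_range[0], g.se_len_range[1] + 1))
        if length >= g.chrom_len:
            raise ValueError("chromosome too short for requested SE length")
        start = int(rng.integers(0, g.chrom_len - length))
        ses.append(GenomicInterval(chrom, start, start + length, f"SE{i + 1:04d}"))

    n_overlap = round(g.se_overlap_fraction * g.n_genes)
    truth = SimTruth()
    genes: list[GeneModel] = []
    se_by_chrom: dict[str, list[GenomicInterval]] = {}
    for se in ses:
        se_by_chrom.setdefault(se.chrom, []).append(se)

    def gene_model(gene_id, chrom, start, length, strand):
        span = GenomicInterval(chrom, start, start + length, gene_id, strand)
        exon1_end = start + max(1, length // 3)
        exon2_start = min(start + length - 1, start + length // 2)
        exons = (
            GenomicInterval(chrom, start, exon1_end, f"{gene_id}_exon1", strand),
            GenomicInterval(chrom, exon2_start, start + length, f"{gene_id}_exon2", strand),
        )
        return GeneModel(gene_id, chrom, strand, span, "lncRNA", exons)

    for i in range(g.n_genes):
        gene_id = f"GENE{i + 1:04d}"
        length = int(rng.integers(g.gene_len_range[0], g.gene_len_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        if i < n_overlap:
            if not ses:
                raise ValueError("cannot plant overlaps without SEs")
            se = ses[rng.integers(len(ses))]
            lo = max(0, se.start - length + 1)
            hi = min(se.end - 1, g.chrom_len - length)
            if hi < lo:
                raise ValueError("chromosome too short to place overlapping gene")
            start = int(rng.integers(lo, hi + 1))
            genes.append(gene_model(gene_id, se.chrom, start, length, strand))
            truth.se_lncrna_ids.add(gene_id)
            truth.se_pairs.append((gene_id, se.name))
        else:
            for _attempt in range(10000):
                chrom = f"chr{rng.integers(1, g.n_chroms + 1)}"
                start = int(rng.integers(0, g.chrom_len - length))
                candidate = GenomicInterval(chrom, start, start + length, gene_id)
                if all(candidate.overlap_bp(se) == 0
                       for se in se_by_chrom.get(chrom, ())):
                    genes.append(gene_model(gene_id, chrom, start, length, strand))
                    break
            else:
                raise ValueError("chromosome too crowded to place non-overlapping gene")
    # overlap-planted genes may graze extra SEs; record every true pair
    truth.se_pairs = []
    for gene in genes:
        if gene.gene_id not in truth.se_lncrna_ids:
            continue
        for se in se_by_chrom.get(gene.chrom, ()):
            if gene.span.overlap_bp(se) >= 1:
                truth.se_pairs.append((gene.gene_id, se.name))
    return ses, genes, truth


def simulate_sequences(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    transcript_ids: list[str] | None = None,
    class_of: dict[str, str] | None = None,
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[SequenceRecord], SimTruth]:
    """Transcripts in three classes (TE-inserted / polyA / background),
    the TE consensus library, and a functional reference sequence set."""
    s = config.sequence
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    te_library = make_te_library()
    consensus = te_library[0]

    if transcript_ids is None:
        transcript_ids = [f"T{i + 1:04d}" for i in range(config.genome.n_genes)]
    n = len(transcript_ids)
    if class_of is None:
        n_te = round(s.class_fractions[0] * n)
        n_polya = round(s.class_fractions[1] * n)
        classes = (["TE"] * n_te + ["polyA"] * n_polya
                   + ["none"] * (n - n_te - n_polya))
        class_of = dict(zip(transcript_ids, classes))

    truth = SimTruth()
    transcripts: list[SequenceRecord] = []
    for tid in transcript_ids:
        klass = class_of[tid]
        background = random_sequence(s.transcript_len, rng, s.base_composition)
        if klass == "TE":
            frag_len = int(rng.integers(s.te_len_range[0],
                                        min(s.te_len_range[1], len(consensus.seq)) + 1))
            if frag_len > s.transcript_len:
                raise ValueError("TE insertion longer than transcript background")
            t_start = int(rng.integers(0, len(consensus.seq) - frag_len + 1))
            fragment = consensus.seq[t_start:t_start + frag_len]
            mutated, _ = mutate_sequence(fragment, s.substitution_rate,
                                         s.indel_rate, rng)
            pos = int(rng.integers(0, s.transcript_len + 1))
            seq = background[:pos] + mutated + background[pos:]
            truth.ridl_coords[tid] = (pos, pos + len(mutated))
        elif klass == "polyA":
            if s.polya_len > s.transcript_len:
                raise ValueError("polyA run longer than transcript background")
            pos = int(rng.integers(0, s.transcript_len + 1))
            seq = background[:pos] + "A" * s.polya_len + background[pos:]
            truth.ridl_coords[tid] = (pos, pos + s.polya_len)
        else:
            seq = background
        truth.ridl_class[tid] = klass
        transcripts.append(SequenceRecord(tid, seq))

    functional_ref = [
        SequenceRecord(f"FUNC{i + 1:03d}",
                       random_sequence(s.functional_ref_len, rng, s.base_composition))
        for i in range(s.n_functional_ref)
    ]
    return transcripts, te_library, functional_ref, truth


def simulate_expression_survival(
    config: SimConfig,
    feature_ids: list[str],
    rng: np.random.Generator | None = None,
    de_features: dict[str, set[str]] | None = None,
    prognostic_features: list[str] | None = None,
) -> tuple[ExpressionMatrix, ClinicalTable, pd.DataFrame, SimTruth]:
    """Expression with planted subtype shifts plus exponential survival
    driven by planted prognostic features; censoring tuned to target."""
    e, sv = config.expression, config.survival
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    subtypes = list(e.subtypes)
    if not subtypes or e.n_per_subtype < 1:
        raise ValueError("every subtype needs at least one sample")
    p = len(feature_ids)
    labels = [s for s in subtypes for _ in range(e.n_per_subtype)]
    n = len(labels)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    if de_features is None:
        de_features = {}
        pool = list(feature_ids)
        for s in subtypes:
            chosen = rng.choice(len(pool), size=min(e.n_de_per_subtype, p),
                                replace=False)
            de_features[s] = {pool[int(i)] for i in chosen}

    baseline = rng.normal(e.baseline_mean, e.baseline_sd, size=p)
    means = np.tile(baseline[:, None], (1, n))
    fidx = {f: i for i, f in enumerate(feature_ids)}
    label_arr = np.array(labels)
    for s, feats in de_features.items():
        cols = label_arr == s
        for f in feats:
            means[fidx[f], cols] += e.shift
    values = means + rng.normal(0.0, e.noise_sd, size=(p, n))
    matrix = ExpressionMatrix(list(feature_ids), sample_ids, values, "log2")

    centroid_vals = np.zeros((p, len(subtypes)))
    for j, s in enumerate(subtypes):
        centroid_vals[:, j] = baseline
        for f in de_features.get(s, ()):
            centroid_vals[fidx[f], j] += e.shift
    centroids = pd.DataFrame(centroid_vals, index=feature_ids, columns=subtypes)

    if prognostic_features is None:
        chosen = rng.choice(p, size=min(sv.n_prognostic, p), replace=False)
        prognostic_features = [feature_ids[int(i)] for i in chosen]
    beta = {f: sv.beta for f in prognostic_features}
    prog_rows = np.array([fidx[f] for f in prognostic_features], dtype=int)
    Xp = values[prog_rows].T  # sample x prognostic feature
    Xp = (Xp - Xp.mean(axis=0)) / np.maximum(Xp.std(axis=0), 1e-12)
    lp = Xp @ np.array([beta[f] for f in prognostic_features])
    rate = sv.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)

    if sv.censoring_fraction > 0:
        u = rng.random(n)
        lo, hi = 1e-9, float(t_event.max()) * 100.0

        def frac_censored(umax: float) -> float:
            return float((u * umax < t_event).mean())

        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if frac_censored(mid) > sv.censoring_fraction:
                lo = mid
            else:
                hi = mid
        c_times = u * np.sqrt(lo * hi)
        event = (t_event <= c_times).astype(int)
        time = np.minimum(t_event, c_times)
    else:
        event = np.ones(n, dtype=int)
        time = t_event
    time = np.maximum(time, 1e-6)
    if event.sum() == 0:
        event[int(np.argmin(time))] = 1  # degenerate configs still need >= 1 event

    clinical = ClinicalTable(sample_ids, time, event, subtype=labels)
    truth = SimTruth(de_features=de_features, prognostic_beta=beta,
                     linear_predictor=lp)
    return matrix, clinical, centroids, truth


# ---------------------------------------------------------------------------
# Orchestrated bundle
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimConfig, out_dir: str | Path | None = None) -> SimBundle:
    """Generate every input with coordinated planted truth.

    With ``planted_hit=True`` the first SE-overlapping gene is the unique
    gene that is simultaneously SE-associated, TE-inserted,
    differentially expressed in the target subtype, and prognostic
    (TE insertions are otherwise restricted to non-SE genes, so no other
    gene can satisfy all four conditions).
    """
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    rng_ann = np.random.default_rng(seeds[0])
    rng_seq = np.random.default_rng(seeds[1])
    rng_expr = np.random.default_rng(seeds[2])

    ses, genes, truth = simulate_annotation(config, rng_ann)
    gene_ids = [g.gene_id for g in genes]
    se_ids = sorted(truth.se_lncrna_ids)

    s = config.sequence
    n = len(gene_ids)
    n_te = round(s.class_fractions[0] * n)
    n_polya = round(s.class_fractions[1] * n)
    class_of: dict[str, str] = {}
    if config.planted_hit and se_ids:
        hit = se_ids[0]
        truth.hit_gene = hit
        non_se = [g for g in gene_ids if g not in truth.se_lncrna_ids]
        te_rest = [non_se[int(i)] for i in
                   rng_seq.choice(len(non_se), size=min(n_te - 1, len(non_se)),
                                  replace=False)] if n_te > 1 else []
        te_genes = {hit, *te_rest}
        remaining = [g for g in gene_ids if g not in te_genes]
        polya_pick = rng_seq.choice(len(remaining), size=min(n_polya, len(remaining)),
                                    replace=False)
        polya_genes = {remaining[int(i)] for i in polya_pick}
        for g in gene_ids:
            class_of[g] = ("TE" if g in te_genes
                           else "polyA" if g in polya_genes else "none")
    else:
        classes = (["TE"] * n_te + ["polyA"] * n_polya
                   + ["none"] * (n - n_te - n_polya))
        perm = rng_seq.permutation(n)
        class_of = {gene_ids[int(i)]: classes[j] for j, i in enumerate(perm)}

    transcripts, te_library, functional_ref, seq_truth = simulate_sequences(
        config, rng_seq, transcript_ids=gene_ids, class_of=class_of
    )
    truth.ridl_class = seq_truth.ridl_class
    truth.ridl_coords = seq_truth.ridl_coords

    e = config.expression
    de_features = None
    prognostic = None
    if config.planted_hit and truth.hit_gene is not None:
        de_features = {}
        pool = list(gene_ids)
        for sub in e.subtypes:
            chosen = {pool[int(i)] for i in
                      rng_expr.choice(len(pool), size=min(e.n_de_per_subtype, n),
                                      replace=False)}
            if sub == e.target_subtype:
                chosen.add(truth.hit_gene)
            de_features[sub] = chosen
        others = [g for g in gene_ids if g != truth.hit_gene]
        extra = [others[int(i)] for i in
                 rng_expr.choice(len(others),
                                 size=min(config.survival.n_prognostic - 1, len(others)),
                                 replace=False)]
        prognostic = [truth.hit_gene, *extra]

    expression, clinical, centroids, expr_truth = simulate_expression_survival(
        config, gene_ids, rng_expr, de_features=de_features,
        prognostic_features=prognostic,
    )
    truth.de_features = expr_truth.de_features
    truth.prognostic_beta = expr_truth.prognostic_beta
    truth.linear_predictor = expr_truth.linear_predictor

    bundle = SimBundle(config, ses, genes, transcripts, te_library,
                       functional_ref, expression, clinical, centroids, truth)
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: SimBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_bed(bundle.se_intervals, out / "se.bed")
    write_gtf(bundle.gene_models, out / "genes.gtf")
    write_fasta(bundle.transcripts, out / "transcripts.fa")
    write_fasta(bundle.te_library, out / "te.fa")
    write_fasta(bundle.functional_ref, out / "functional_ref.fa")
    write_matrix(bundle.expression, out / "expr.tsv")
    write_clinical(bundle.clinical, out / "clinical.tsv")
    centroids = bundle.centroids.copy()
    centroids.index.name = "feature"
    centroids.to_csv(out / "centroids.tsv", sep="\t", float_format="%.10g")

    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    t = bundle.truth
    pd.DataFrame(sorted(t.se_pairs), columns=["gene_id", "se_name"]).to_csv(
        truth_dir / "se_pairs.tsv", sep="\t", index=False)
    rows = [(tid, t.ridl_class[tid], *(t.ridl_coords.get(tid, ("", ""))))
            for tid in sorted(t.ridl_class)]
    pd.DataFrame(rows, columns=["transcript_id", "class", "start", "end"]).to_csv(
        truth_dir / "ridl.tsv", sep="\t", index=False)
    de_rows = [(s, f) for s, feats in sorted(t.de_features.items())
               for f in sorted(feats)]
    pd.DataFrame(de_rows, columns=["subtype", "feature"]).to_csv(
        truth_dir / "de_features.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(t.prognostic_beta.items()),
                 columns=["feature", "beta"]).to_csv(
        truth_dir / "prognostic.tsv", sep="\t", index=False)
    if t.hit_gene is not None:
        (truth_dir / "hit_gene.txt").write_text(t.hit_gene + "\n")


def validate_bundle(bundle: SimBundle) -> None:
    """Check that the truth tables are consistent with the emitted data."""
    truth = bundle.truth
    se_index = {}
    for se in bundle.se_intervals:
        se_index.setdefault(se.chrom, []).append(se)
    for gene in bundle.gene_models:
        overlaps = any(gene.span.overlap_bp(se) >= 1
                       for se in se_index.get(gene.chrom, ()))
        planted = gene.gene_id in truth.se_lncrna_ids
        if overlaps != planted:
            raise AssertionError(
                f"SE-overlap truth inconsistent for {gene.gene_id}")
    seq_of = {t.id: t.seq for t in bundle.transcripts}
    for tid, klass in truth.ridl_class.items():
        if tid not in seq_of:
            raise AssertionError(f"truth transcript {tid} missing from FASTA")
        if klass == "polyA":
            s, e = truth.ridl_coords[tid]
            run = seq_of[tid][s:e]
            if run.count("A") / len(run) < 0.9:
                raise AssertionError(f"planted polyA run missing in {tid}")
    for feats in truth.de_features.values():
        missing = feats - set(bundle.expression.feature_ids)
        if missing:
            raise AssertionError(f"planted DE features missing: {missing}")
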