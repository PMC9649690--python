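"""Synthetic inputs with planted ground truth for every pipeline stage.

Real inputs for this kind of analysis are consortium-scale (pan-cancer
RNA-seq atlases, knockdown + binding assays per RBP, drug-response panels).
This module emulates their statistical structure at desk scale so that
every downstream stage can be exercised against a known truth:

* **Expression atlas** — lognormal TPM with per-cell dropout; planted
  lineage-specific transcripts have their home-lineage mean boosted so the
  home lineage holds a target share (``specific_ratio``) of the
  lineage-summed expression; optional exactly-constant null transcripts
  give perfectly uniform lineage profiles.
* **Drug response** — AUC values linearly driven by a few standardized
  driver transcripts (signed effects) plus Gaussian noise.
* **Regulome** — per-RBP knockdown DE tables with planted regulated
  transcripts passing the |FC| > 1.5 & FDR < 0.05 filter, and binding
  peaks placed inside exons of a controlled fraction of the regulated
  transcripts; decoy peaks fall in intergenic gaps so the recoverable edge
  set equals exactly the planted (regulated AND bound) pairs.
* **Annotation fixture** — a small reference/query GTF pair covering every
  classification category, a two-gene readthrough, and CAGE/chromatin
  peaks at controlled distances (0 / 500 / 501 nt) from selected TSSs.

All generators are pure functions of their config (including the seed):
the same config yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import BED_COLUMNS, TranscriptModel
from .atlas import ExpressionAtlas
from .errors import ConfigurationError

__all__ = [
    "AtlasSimConfig",
    "DrugSimConfig",
    "RegulomeSimConfig",
    "AnnotationSimConfig",
    "GroundTruth",
    "simulate_expression_atlas",
    "simulate_drug_response",
    "simulate_regulome",
    "simulate_annotation",
    "make_transcript_models",
]


@dataclass
class GroundTruth:
    """Planted truth: what each generator hid in its output."""

    specific_transcripts: dict[str, str] = field(default_factory=dict)
    drug_drivers: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    regulated: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    bound: dict[str, list[str]] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)
    readthrough: dict[str, bool] = field(default_factory=dict)
    expected_names: dict[str, str] = field(default_factory=dict)
    evidence_labels: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "specific_transcripts": self.specific_transcripts,
            "drug_drivers": {
                d: [[t, s] for t, s in pairs]
                for d, pairs in self.drug_drivers.items()
            },
            "regulated": {
                r: [[t, d] for t, d in pairs]
                for r, pairs in self.regulated.items()
            },
            "bound": self.bound,
            "categories": self.categories,
            "readthrough": self.readthrough,
            "expected_names": self.expected_names,
            "evidence_labels": self.evidence_labels,
        }


# --------------------------------------------------------------------------
# expression atlas


@dataclass
class AtlasSimConfig:
    """Atlas generator settings.

    ``specific_ratio`` is the target share of a planted transcript's
    lineage-summed expression falling in its home lineage; the home-lineage
    mean is boosted by ratio*(N-1)/(1-ratio) relative to the others, which
    achieves that share in expectation. ``baseline_log_mean`` /
    ``baseline_log_sd`` parameterise log2-normal TPM (TPM = 2**N(mu, sd));
    dropout multiplies each entry by an independent Bernoulli(1 - p).
    ``n_constant_null`` transcripts get an identical TPM in every cell,
    i.e. an exactly uniform lineage profile (score exactly 0).
    """

    n_transcripts: int = 2000
    n_cell_lines: int = 110
    n_lineages: int = 22
    n_planted_specific: int = 200
    specific_ratio: float = 0.8
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    dropout_prob: float = 0.2
    n_constant_null: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_lineages < 2:
            raise ConfigurationError("need at least 2 lineages")
        if self.n_cell_lines < 2 * self.n_lineages:
            raise ConfigurationError(
                "each lineage needs >= 2 cell lines: "
                f"{self.n_cell_lines} cells for {self.n_lineages} lineages"
            )
        if self.n_planted_specific + self.n_constant_null > self.n_transcripts:
            raise ConfigurationError("more planted transcripts than transcripts")
        if not 0 < self.specific_ratio <= 1:
            raise ConfigurationError("specific_ratio must lie in (0, 1]")
        if not 0 <= self.dropout_prob <= 1:
            raise ConfigurationError("dropout_prob must lie in [0, 1]")


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def simulate_expression_atlas(
    cfg: AtlasSimConfig,
) -> tuple[ExpressionAtlas, GroundTruth]:
    """Generate a TPM atlas with planted lineage-specific transcripts."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_t, n_c, n_l = cfg.n_transcripts, cfg.n_cell_lines, cfg.n_lineages
    transcripts = _ids("TX", n_t)
    cells = _ids("CL", n_c)
    lineages = [f"lineage{i:02d}" for i in range(1, n_l + 1)]
    # round-robin assignment keeps lineages balanced (>= 2 cells each)
    lineage_of = pd.Series(
        [lineages[i % n_l] for i in range(n_c)], index=cells, name="lineage"
    )

    mu = rng.normal(cfg.baseline_log_mean, 0.5, size=n_t)
    log_tpm = rng.normal(mu[:, None], cfg.baseline_log_sd, size=(n_t, n_c))
    values = np.power(2.0, log_tpm)

    truth = GroundTruth()
    planted = rng.choice(n_t, size=cfg.n_planted_specific, replace=False)
    homes = rng.integers(0, n_l, size=cfg.n_planted_specific)
    if cfg.specific_ratio < 1:
        boost = cfg.specific_ratio * (n_l - 1) / (1 - cfg.specific_ratio)
    else:
        boost = np.inf
    lineage_idx = np.array([lineages.index(l) for l in lineage_of])
    for t_idx, home in zip(planted, homes):
        in_home = lineage_idx == home
        if np.isinf(boost):
            values[t_idx, ~in_home] = 0.0
        else:
            values[t_idx, in_home] *= boost
        truth.specific_transcripts[transcripts[t_idx]] = lineages[home]

    if cfg.n_constant_null:
        pool = np.setdiff1d(np.arange(n_t), planted)
        const = rng.choice(pool, size=cfg.n_constant_null, replace=False)
        values[const, :] = np.power(
            2.0, rng.normal(cfg.baseline_log_mean, 0.5, size=cfg.n_constant_null)
        )[:, None]
    else:
        const = np.array([], dtype=int)

    if cfg.dropout_prob > 0:
        keep = rng.random(size=(n_t, n_c)) >= cfg.dropout_prob
        keep[const, :] = True  # constant nulls stay exactly uniform
        values = values * keep

    atlas = ExpressionAtlas(
        pd.DataFrame(values, index=transcripts, columns=cells), lineage_of
    )
    return atlas, truth


# --------------------------------------------------------------------------
# drug response


@dataclass
class DrugSimConfig:
    """Drug-panel generator: AUC = center + scale * (signal + noise), with
    signal = sum over drivers of effect_size * sign * z(driver expression).
    Drivers are drawn from transcripts detected (TPM > 0.1) in at least 20%
    of cell lines, matching the prevalence filter the association stage
    applies."""

    n_drugs: int = 8
    n_driver_transcripts_per_drug: int = 5
    effect_size: float = 1.0
    noise_sd: float = 1.0
    auc_center: float = 12.0
    auc_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_drugs < 1 or self.n_driver_transcripts_per_drug < 0:
            raise ConfigurationError("drug/driver counts must be positive")


def simulate_drug_response(
    atlas: ExpressionAtlas, cfg: DrugSimConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a cell line x drug AUC matrix driven by planted transcripts."""
    cfg.validate()
    if atlas.values.empty:
        raise ConfigurationError("atlas is empty")
    rng = np.random.default_rng(cfg.seed)
    expr = atlas.values.to_numpy(dtype=float)
    n_t, n_c = expr.shape
    prevalent = np.flatnonzero((expr > 0.1).sum(axis=1) >= 0.2 * n_c)
    if cfg.n_driver_transcripts_per_drug > 0 and len(prevalent) < (
        cfg.n_driver_transcripts_per_drug
    ):
        raise ConfigurationError(
            "driver pool empty/too small after the 20% prevalence filter"
        )
    sd = expr.std(axis=1, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (expr - expr.mean(axis=1, keepdims=True)) / sd[:, None]
    z = np.nan_to_num(z)

    drugs = _ids("DRUG", cfg.n_drugs)
    truth = GroundTruth()
    auc = np.empty((n_c, cfg.n_drugs))
    tids = list(atlas.transcript_ids)
    for j, drug in enumerate(drugs):
        signal = np.zeros(n_c)
        pairs = []
        if cfg.n_driver_transcripts_per_drug > 0:
            drivers = rng.choice(
                prevalent, size=cfg.n_driver_transcripts_per_drug, replace=False
            )
            signs = rng.choice([-1, 1], size=len(drivers))
            for t_idx, s in zip(drivers, signs):
                signal += cfg.effect_size * s * z[t_idx]
                pairs.append((tids[t_idx], int(s)))
        noise = rng.normal(0.0, cfg.noise_sd, size=n_c)
        auc[:, j] = cfg.auc_center + cfg.auc_scale * (signal + noise)
        truth.drug_drivers[drug] = pairs
    return (
        pd.DataFrame(auc, index=atlas.cell_line_ids, columns=drugs),
        truth,
    )


# --------------------------------------------------------------------------
# transcript models + regulome


def make_transcript_models(
    transcript_ids, seed: int = 0, n_chroms: int = 4
) -> dict[str, TranscriptModel]:
    """Lay out one simple multi-exon gene model per transcript, spaced along
    synthetic chromosomes with wide intergenic gaps (where decoy peaks go)."""
    rng = np.random.default_rng(seed)
    models: dict[str, TranscriptModel] = {}
    cursors = {f"chr{c + 1}": 10_000 for c in range(n_chroms)}
    for i, tid in enumerate(transcript_ids):
        chrom = f"chr{i % n_chroms + 1}"
        pos = cursors[chrom]
        n_exons = int(rng.integers(2, 5))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(150, 400))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(200, 800))
        cursors[chrom] = pos + 5_000  # intergenic gap
        strand = "+" if rng.random() < 0.5 else "-"
        models[tid] = TranscriptModel(
            id=tid, gene_ids=(f"G_{tid}",), chrom=chrom, strand=strand,
            exons=tuple(exons),
        )
    return models


@dataclass
class RegulomeSimConfig:
    """Knockdown-DE + binding-peak generator.

    Planted regulated transcripts get |log2FC| of at least ``lfc_effect``
    and FDR below 0.05; null transcripts get small fold changes and FDR at
    or above ``null_fdr_floor`` so they can never pass the significance
    filter. ``frac_bound_of_regulated`` of each RBP's planted transcripts
    receive a binding peak inside one of their exons; decoy peaks land in
    intergenic gaps.
    """

    n_rbps: int = 6
    n_regulated_per_rbp: int = 30
    frac_bound_of_regulated: float = 0.7
    lfc_effect: float = 1.0  # log2 scale; > log2(1.5) to pass the filter
    null_fdr_floor: float = 0.05
    n_decoy_peaks_per_rbp: int = 20
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.frac_bound_of_regulated <= 1:
            raise ConfigurationError("frac_bound_of_regulated must be in [0,1]")
        if self.n_rbps < 1 or self.n_regulated_per_rbp < 0:
            raise ConfigurationError("RBP counts must be positive")


def simulate_regulome(
    transcript_ids,
    cfg: RegulomeSimConfig,
    models: dict[str, TranscriptModel],
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], GroundTruth]:
    """Generate per-RBP DE tables and BED peak frames plus planted truth."""
    cfg.validate()
    transcript_ids = list(transcript_ids)
    missing = [t for t in transcript_ids if t not in models]
    if missing:
        raise ConfigurationError(
            f"models missing for transcripts: {missing[:5]}"
        )
    if cfg.n_regulated_per_rbp > len(transcript_ids):
        raise ConfigurationError("more regulated transcripts than transcripts")
    rng = np.random.default_rng(cfg.seed)
    rbps = [f"RBP{i:02d}" for i in range(1, cfg.n_rbps + 1)]
    de_set: dict[str, pd.DataFrame] = {}
    peak_set: dict[str, pd.DataFrame] = {}
    truth = GroundTruth()
    chrom_ends: dict[str, int] = {}
    for m in models.values():
        chrom_ends[m.chrom] = max(chrom_ends.get(m.chrom, 0), m.span[1])

    for rbp in rbps:
        reg_idx = rng.choice(
            len(transcript_ids), size=cfg.n_regulated_per_rbp, replace=False
        )
        regulated = [transcript_ids[i] for i in sorted(reg_idx)]
        directions = rng.choice(["up", "down"], size=len(regulated))
        lfc = np.zeros(len(transcript_ids))
        fdr = np.empty(len(transcript_ids))
        is_reg = np.zeros(len(transcript_ids), dtype=bool)
        is_reg[reg_idx] = True
        # nulls: small fold changes, FDR at/above the floor (never significant)
        lfc[~is_reg] = rng.normal(0.0, 0.15, size=(~is_reg).sum())
        fdr[~is_reg] = rng.uniform(cfg.null_fdr_floor, 1.0, size=(~is_reg).sum())
        pairs = []
        for i, (idx, d) in enumerate(zip(sorted(reg_idx), directions)):
            magnitude = cfg.lfc_effect * (1.0 + rng.uniform(0.0, 0.3))
            lfc[idx] = magnitude if d == "up" else -magnitude
            fdr[idx] = rng.uniform(0.0, 0.04)
            pairs.append((transcript_ids[idx], str(d)))
        truth.regulated[rbp] = pairs
        de_set[rbp] = pd.DataFrame(
            {"transcript_id": transcript_ids, "log2fc": lfc,
             "pvalue": fdr * 0.5, "fdr": fdr}
        )

        n_bound = int(round(cfg.frac_bound_of_regulated * len(regulated)))
        bound = [regulated[i] for i in rng.choice(
            len(regulated), size=n_bound, replace=False
        )]
        truth.bound[rbp] = sorted(bound)
        rows = []
        for tid in bound:
            m = models[tid]
            a, b = m.exons[int(rng.integers(0, len(m.exons)))]
            width = min(int(rng.integers(30, 80)), b - a)
            start1 = int(rng.integers(a, b - width + 1))  # 1-based
            rows.append({
                "chrom": m.chrom, "start": start1 - 1, "end": start1 - 1 + width,
                "name": f"{rbp}_{tid}", "score": 100, "strand": m.strand,
            })
        for k in range(cfg.n_decoy_peaks_per_rbp):
            chrom = str(rng.choice(sorted(chrom_ends)))
            start0 = chrom_ends[chrom] + 10_000 + int(rng.integers(0, 50_000))
            rows.append({
                "chrom": chrom, "start": start0, "end": start0 + 50,
                "name": f"{rbp}_decoy{k}", "score": 10, "strand": ".",
            })
        peak_set[rbp] = pd.DataFrame(rows, columns=BED_COLUMNS)
    return de_set, peak_set, truth


# --------------------------------------------------------------------------
# annotation fixture


@dataclass
class AnnotationSimConfig:
    """Fixture layout for the classifier; the construction is deterministic
    (coordinates are fixed by design, not sampled)."""

    tss_window: int = 500
    seed: int = 0


def simulate_annotation(
    cfg: AnnotationSimConfig | None = None,
) -> tuple[list[TranscriptModel], list[TranscriptModel], pd.DataFrame,
           pd.DataFrame, GroundTruth]:
    """Build (reference models, query models, CAGE peaks, chromatin peaks,
    truth) covering every classification category, one readthrough, and
    TSS-evidence boundary cases at 0 / 500 / 501 nt."""
    cfg = cfg or AnnotationSimConfig()

    ga = TranscriptModel(
        "REF_GA_T1", ("GA",), "chr1", "+",
        ((1001, 1200), (1501, 1700), (2001, 2200)),
    )
    gb = TranscriptModel("REF_GB_T1", ("GB",), "chr1", "+",
                         ((5001, 5200), (5401, 5600)))
    gc = TranscriptModel("REF_GC_T1", ("GC",), "chr1", "-",
                         ((8001, 8200), (8401, 8600)))
    reference = [ga, gb, gc]

    def q(tid, exons, strand="+"):
        return TranscriptModel(tid, (tid,), "chr1", strand, exons)

    queries = [
        q("Q_MATCH", ((1001, 1200), (1501, 1700), (2001, 2200))),
        q("Q_CONTAIN", ((601, 700), (1001, 1200), (1501, 1700), (2001, 2200))),
        q("Q_JUNCTION", ((1001, 1200), (1501, 1800))),
        q("Q_RETAIN", ((1101, 1600),)),
        q("Q_OVERLAP", ((1105, 1300),)),
        q("Q_WITHIN", ((1251, 1450),)),
        q("Q_READTHROUGH", ((2001, 2200), (5001, 5200))),
        q("Q_INTERGENIC", ((12001, 12500),)),
        q("Q_INTERGENIC2", ((14001, 14400),)),
        q("Q_INTERGENIC3", ((16001, 16400),)),
        q("Q_INTERGENIC4", ((18001, 18400),)),
    ]
    truth = GroundTruth(
        categories={
            "Q_MATCH": "annotated_match",
            "Q_CONTAIN": "contain_Ref",
            "Q_JUNCTION": "match_Refjunction",
            "Q_RETAIN": "retain_Refintron",
            "Q_OVERLAP": "overlap_Refexon",
            "Q_WITHIN": "within_Refintron",
            "Q_READTHROUGH": "overlap_Refexon",
            "Q_INTERGENIC": "intergenic",
            "Q_INTERGENIC2": "intergenic",
            "Q_INTERGENIC3": "intergenic",
            "Q_INTERGENIC4": "intergenic",
        },
        readthrough={t.id: t.id == "Q_READTHROUGH" for t in queries},
        expected_names={
            "Q_MATCH": "GA-a1",
            "Q_CONTAIN": "GA-u1",
            "Q_JUNCTION": "GA-u2",
            "Q_RETAIN": "GA-u3",
            "Q_OVERLAP": "GA-u4",
            "Q_WITHIN": "GA-u5",
            "Q_READTHROUGH": "Q_READTHROUGH",  # spans two genes: keeps its id
            "Q_INTERGENIC": "Q_INTERGENIC",
            "Q_INTERGENIC2": "Q_INTERGENIC2",
            "Q_INTERGENIC3": "Q_INTERGENIC3",
            "Q_INTERGENIC4": "Q_INTERGENIC4",
        },
        # TSS positions: all the GA-locus queries have TSSs within 500 nt of
        # the peaks planted at the GA promoter, hence "both"; the isolated
        # intergenic queries carry the boundary and single-assay cases.
        evidence_labels={
            "Q_MATCH": "both",
            "Q_CONTAIN": "both",       # TSS 601, peaks at 1001/1101 in range
            "Q_JUNCTION": "both",      # shares the TSS at 1001 with Q_MATCH
            "Q_RETAIN": "both",
            "Q_OVERLAP": "both",
            "Q_WITHIN": "both",
            "Q_READTHROUGH": "none",   # TSS 2001, nearest peak 750 nt away
            "Q_INTERGENIC": "cage_only",  # CAGE exactly at the 500 nt boundary
            "Q_INTERGENIC2": "none",
            "Q_INTERGENIC3": "chromatin_only",
            "Q_INTERGENIC4": "both",
        },
    )
    # BED (0-based half-open). 1-based base x -> [x-1, x).
    cage = pd.DataFrame(
        [
            ("chr1", 1000, 1001, "cage_at_GA_tss", 0, "."),     # 0 nt from 1001
            ("chr1", 1250, 1251, "cage_at_QWITHIN", 0, "."),    # 0 nt from 1251
            ("chr1", 11500, 11501, "cage_500_upstream", 0, "."),  # 500 nt from 12001
            ("chr1", 18000, 18001, "cage_at_QI4", 0, "."),
        ],
        columns=BED_COLUMNS,
    )
    chromatin = pd.DataFrame(
        [
            ("chr1", 1000, 1001, "chrom_at_GA_tss", 0, "."),
            ("chr1", 1100, 1101, "chrom_at_1101", 0, "."),      # hits 1101/1105 TSS
            ("chr1", 11499, 11500, "chrom_501_upstream", 0, "."),  # 501 nt: no call
            ("chr1", 16000, 16001, "chrom_at_QI3", 0, "."),
            ("chr1", 18000, 18001, "chrom_at_QI4", 0, "."),
        ],
        columns=BED_COLUMNS,
    )
    return reference, queries, cage, chromatin, truth
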