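"""Synthetic tumor cohort generator with a ground-truth ledger.

Emulates the statistical structure of a pan-cancer copy-number / SV /
expression cohort at a single engineered locus triplet: a driver oncogene
(CCNE1-analog), a dosage-sensitive target gene (BRD4-analog) whose
exon1-intron1 window recurrently acquires small nested deletions, and a
neighbor gene (NOTCH3-analog) used for copy-number normalization.

The genome model is one synthetic ~5 Mbp chromosome. Each sample draws a
tumor type, optionally a large amplification spanning all three loci, and
optionally a focal deletion (< 100 kbp) nested inside the target window.
The generative event order (amplification-first vs deletion-first) and the
haplotype hit by the deletion are recorded in the truth ledger, and the
emitted allelic copy numbers are consistent with that history:

* amplification first, deletion on the amplified haplotype: inside the
  deletion the amplified haplotype keeps a non-zero copy number (one copy
  of its local state removed);
* deletion first on the haplotype that later amplifies: all amplified
  copies carry the deletion, so the amplified haplotype drops to zero
  inside the deletion (loss of heterozygosity);
* deletion on the unamplified haplotype: the allelic pattern is identical
  under either order, so the sample is generatively uninformative for
  timing.

Read depth is emitted as tumor/normal ratios over 200-bp bins with
negative-binomial counting noise; expression follows a linear dosage
model (tumor-type baseline + slope x copy number + focal-deletion offset)
with Gaussian noise clamped at zero.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    CopyNumberSegment,
    ExpressionTable,
    GeneLocus,
    ReadDepthTrack,
    SampleTable,
    SVJunction,
)

# --- synthetic genome -------------------------------------------------------

CHROM = "chrS"
CHROM_LENGTH = 5_000_000

DRIVER_LOCUS = GeneLocus("CCNE1L", CHROM, 2_000_000, 2_035_000)
TARGET_LOCUS = GeneLocus("BRD4L", CHROM, 3_000_000, 3_092_000, window=(3_005_000, 3_085_000))
NEIGHBOR_LOCUS = GeneLocus("NOTCH3L", CHROM, 3_150_000, 3_200_000)
DEFAULT_LOCI = [DRIVER_LOCUS, TARGET_LOCUS, NEIGHBOR_LOCUS]

AMP_INTERVAL = (1_900_000, 3_400_000)  # spans driver, target and neighbor
# the amplicon peaks over the driver oncogene and carries a lower shoulder
# across the target/neighbor pair (driver-centred amplification)
DRIVER_PEAK = (1_900_000, 2_500_000)
DEPTH_REGION = (2_900_000, 3_300_000)  # depth emitted around target/neighbor

TUMOR_TYPES = ("BRCA", "OV", "UCEC", "Other")

# isoform structure of the target gene: one long and two short transcripts,
# the secondary short isoform expressed far below the dominant one
ISOFORM_FRACTIONS = {"long": 0.70, "short_a": 0.25, "short_b": 0.05}


class SimConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass(frozen=True)
class ExpressionModelCoeffs:
    """Generative coefficients of the linear dosage model, FPKM units.

    ``baseline_by_type`` holds absolute per-tumor-type intercepts;
    ``beta_cn`` is FPKM per copy; ``beta_del`` the focal-deletion offset.
    Defaults place the ovarian baseline 26.1 FPKM above the reference
    ('Other') type, with slope 3.6 and deletion offset -6.3.
    """

    baseline_by_type: dict[str, float] = field(
        default_factory=lambda: {"Other": 8.0, "OV": 34.1, "BRCA": 20.0, "UCEC": 17.0}
    )
    beta_cn: float = 3.6
    beta_del: float = -6.3

    def linear_predictor(self, tumor_type: str, cn: float, has_deletion: bool) -> float:
        return (
            self.baseline_by_type[tumor_type]
            + self.beta_cn * cn
            + (self.beta_del if has_deletion else 0.0)
        )


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the cohort generator; every probability in [0, 1]."""

    n_samples: int = 200
    tumor_type_weights: dict[str, float] = field(
        default_factory=lambda: {"BRCA": 0.25, "OV": 0.35, "UCEC": 0.20, "Other": 0.20}
    )
    p_amplification: float = 0.4
    amp_total_cn_range: tuple[int, int] = (3, 10)  # CN at the driver peak
    amp_local_cn_range: tuple[int, int] = (3, 4)   # amplicon shoulder at target/neighbor
    p_focal_del_given_amp: float = 0.5
    p_focal_del_given_no_amp: float = 0.02
    del_length_range: tuple[int, int] = (5_000, 60_000)
    del_window: tuple[int, int] = TARGET_LOCUS.window
    p_deletion_first: float = 0.15
    p_del_on_amp_haplotype: float = 0.8
    depth_dispersion: float = 20.0  # negative-binomial size; inf -> Poisson
    coverage: float = 100.0  # expected normal-sample reads per 200-bp bin
    bin_size: int = 200
    depth_region: tuple[int, int] = DEPTH_REGION
    expr_coeffs: ExpressionModelCoeffs = field(default_factory=ExpressionModelCoeffs)
    expr_noise_sd: float = 5.0
    p_scna_dropout: float = 0.25
    purity: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "p_amplification": self.p_amplification,
            "p_focal_del_given_amp": self.p_focal_del_given_amp,
            "p_focal_del_given_no_amp": self.p_focal_del_given_no_amp,
            "p_deletion_first": self.p_deletion_first,
            "p_del_on_amp_haplotype": self.p_del_on_amp_haplotype,
            "p_scna_dropout": self.p_scna_dropout,
            "purity": self.purity,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise SimConfigError(f"{name} must be in [0,1], got {p}")
        if self.n_samples < 1:
            raise SimConfigError(f"n_samples must be >= 1, got {self.n_samples}")
        if abs(sum(self.tumor_type_weights.values()) - 1.0) > 1e-9:
            raise SimConfigError("tumor_type_weights must sum to 1")
        if any(w < 0 for w in self.tumor_type_weights.values()):
            raise SimConfigError("tumor_type_weights must be non-negative")
        for name in ("amp_total_cn_range", "amp_local_cn_range"):
            lo, hi = getattr(self, name)
            if not (2 < lo <= hi):
                raise SimConfigError(f"{name} must satisfy 2 < lo <= hi, got {lo},{hi}")
        dlo, dhi = self.del_length_range
        ws, we = self.del_window
        if not (0 < dlo <= dhi):
            raise SimConfigError(f"del_length_range must satisfy 0 < lo <= hi, got {dlo},{dhi}")
        if dhi > we - ws:
            raise SimConfigError(
                f"del_length_range max {dhi} exceeds del_window length {we - ws}"
            )
        if dhi >= AMP_INTERVAL[1] - AMP_INTERVAL[0]:
            raise SimConfigError("del_length_range max must be below the amplification length")
        if not (TARGET_LOCUS.start <= ws < we <= TARGET_LOCUS.end):
            raise SimConfigError(f"del_window {self.del_window} not inside the target gene")
        missing = set(self.tumor_type_weights) - set(self.expr_coeffs.baseline_by_type)
        if missing:
            raise SimConfigError(f"expr_coeffs.baseline_by_type missing tumor types {missing}")
        if not np.isfinite(self.expr_coeffs.beta_cn):
            raise SimConfigError("expr_coeffs.beta_cn must be finite")
        if self.depth_dispersion <= 0:
            raise SimConfigError(f"depth_dispersion must be > 0, got {self.depth_dispersion}")
        if self.expr_noise_sd < 0:
            raise SimConfigError(f"expr_noise_sd must be >= 0, got {self.expr_noise_sd}")
        if self.bin_size <= 0 or self.coverage <= 0:
            raise SimConfigError("bin_size and coverage must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        if "expr_coeffs" in data and isinstance(data["expr_coeffs"], dict):
            data["expr_coeffs"] = ExpressionModelCoeffs(**data["expr_coeffs"])
        for key in (
            "amp_total_cn_range",
            "amp_local_cn_range",
            "del_length_range",
            "del_window",
            "depth_region",
        ):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise SimConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


# --- truth ledger -----------------------------------------------------------


@dataclass
class SampleTruth:
    """Generative record for one sample — the oracle every test checks."""

    sample: str
    patient: str
    tumor_type: str
    amp_interval: tuple[int, int] | None
    amp_total_cn: int | None    # amplicon CN at the target/neighbor shoulder
    amp_driver_cn: int | None   # amplicon CN at the driver peak
    del_interval: tuple[int, int] | None
    event_order: str  # 'amp_first' | 'del_first' | 'n/a'
    del_haplotype: str | None  # 'amp' | 'other'
    scna_emitted: bool
    target_locus_cn: float  # true mean total CN across the target gene
    neighbor_locus_cn: float
    driver_locus_cn: float
    expr_mean_target: float  # noiseless linear predictor, pre-clamping
    timing_informative: bool
    ambiguous_reason: str | None

    @property
    def has_amp(self) -> bool:
        return self.amp_interval is not None

    @property
    def has_del(self) -> bool:
        return self.del_interval is not None


@dataclass
class CohortTruth:
    config: SimConfig
    samples: list[SampleTruth]

    def by_sample(self) -> dict[str, SampleTruth]:
        return {t.sample: t for t in self.samples}

    def carriers(self) -> list[SampleTruth]:
        return [t for t in self.samples if t.has_del]

    def to_json(self) -> str:
        payload = {
            "config": self.config.to_dict(),
            "samples": [dataclasses.asdict(t) for t in self.samples],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortTruth":
        payload = json.loads(text)
        config = SimConfig.from_dict(payload["config"])
        samples = []
        for rec in payload["samples"]:
            for key in ("amp_interval", "del_interval"):
                if rec[key] is not None:
                    rec[key] = tuple(rec[key])
            samples.append(SampleTruth(**rec))
        return cls(config, samples)


@dataclass
class SimResult:
    segments: list[CopyNumberSegment]
    junctions: list[SVJunction]
    depth: dict[str, ReadDepthTrack]
    expression: ExpressionTable
    metadata: SampleTable
    truth: CohortTruth


# --- generation -------------------------------------------------------------


def _haplotype_profile(truth: SampleTruth) -> list[tuple[int, int, float, float]]:
    """True per-haplotype copy state as (start, end, hapA, hapB) pieces,
    where hapA is the haplotype that amplifies (if any)."""
    bounds = {0, CHROM_LENGTH}
    if truth.amp_interval:
        bounds.update(truth.amp_interval)
        bounds.add(DRIVER_PEAK[1])
    if truth.del_interval:
        bounds.update(truth.del_interval)
    cuts = sorted(bounds)
    pieces = []
    for s, e in zip(cuts, cuts[1:]):
        a, b = 1.0, 1.0
        in_amp = truth.amp_interval and truth.amp_interval[0] <= s < truth.amp_interval[1]
        in_del = truth.del_interval and truth.del_interval[0] <= s < truth.del_interval[1]
        if in_amp:
            in_peak = DRIVER_PEAK[0] <= s < DRIVER_PEAK[1]
            a = float((truth.amp_driver_cn if in_peak else truth.amp_total_cn) - 1)
        if in_del:
            if truth.del_haplotype == "amp" and in_amp:
                if truth.event_order == "del_first":
                    a = 0.0  # all amplified copies carry the deletion
                else:
                    a -= 1.0  # one copy of the amplified stack removed
            else:
                b = 0.0
        pieces.append((s, e, a, b))
    return pieces


def _true_locus_cn(pieces, locus: GeneLocus) -> float:
    num = den = 0.0
    for s, e, a, b in pieces:
        ov = max(0, min(e, locus.end) - max(s, locus.start))
        if ov:
            num += (a + b) * ov
            den += ov
    return num / den


def simulate_cohort(config: SimConfig) -> SimResult:
    """Generate a full cohort; deterministic for a fixed (config, seed)."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_events, ss_depth, ss_expr = root.spawn(3)
    rng = np.random.default_rng(ss_events)

    types = sorted(config.tumor_type_weights)
    weights = np.array([config.tumor_type_weights[t] for t in types])
    weights = weights / weights.sum()

    truths: list[SampleTruth] = []
    width = max(4, len(str(config.n_samples)))
    for i in range(config.n_samples):
        sample = f"S{i + 1:0{width}d}"
        tumor_type = types[rng.choice(len(types), p=weights)]
        has_amp = rng.random() < config.p_amplification
        amp_cn = amp_driver_cn = None
        if has_amp:
            lo, hi = config.amp_local_cn_range
            amp_cn = int(rng.integers(lo, hi + 1))
            dlo_cn, dhi_cn = config.amp_total_cn_range
            # the driver peak is never below the shoulder
            amp_driver_cn = max(int(rng.integers(dlo_cn, dhi_cn + 1)), amp_cn)
        p_del = config.p_focal_del_given_amp if has_amp else config.p_focal_del_given_no_amp
        has_del = rng.random() < p_del

        del_interval = None
        order = "n/a"
        del_hap = None
        scna_emitted = True
        if has_del:
            dlo, dhi = config.del_length_range
            length = int(rng.integers(dlo, dhi + 1))
            ws, we = config.del_window
            start = int(rng.integers(ws, we - length + 1))
            del_interval = (start, start + length)
            scna_emitted = rng.random() >= config.p_scna_dropout
            if has_amp:
                order = "del_first" if rng.random() < config.p_deletion_first else "amp_first"
                del_hap = "amp" if rng.random() < config.p_del_on_amp_haplotype else "other"
            else:
                del_hap = "other"

        truth = SampleTruth(
            sample=sample,
            patient=f"P{i + 1:0{width}d}",
            tumor_type=tumor_type,
            amp_interval=AMP_INTERVAL if has_amp else None,
            amp_total_cn=amp_cn,
            amp_driver_cn=amp_driver_cn,
            del_interval=del_interval,
            event_order=order,
            del_haplotype=del_hap,
            scna_emitted=scna_emitted,
            target_locus_cn=0.0,
            neighbor_locus_cn=0.0,
            driver_locus_cn=0.0,
            expr_mean_target=0.0,
            timing_informative=False,
            ambiguous_reason=None,
        )
        pieces = _haplotype_profile(truth)
        truth.target_locus_cn = _true_locus_cn(pieces, TARGET_LOCUS)
        truth.neighbor_locus_cn = _true_locus_cn(pieces, NEIGHBOR_LOCUS)
        truth.driver_locus_cn = _true_locus_cn(pieces, DRIVER_LOCUS)
        truth.expr_mean_target = config.expr_coeffs.linear_predictor(
            tumor_type, truth.target_locus_cn, has_del
        )
        if truth.has_amp and truth.has_del:
            if not truth.scna_emitted:
                # no segment-level CN call: the deletion never registers
                # on allelic copy number, whichever haplotype it hit
                truth.ambiguous_reason = "deletion_below_allelic_resolution"
            elif truth.del_haplotype != "amp":
                truth.ambiguous_reason = "different_alleles"
            else:
                truth.timing_informative = True
        truths.append(truth)

    segments = []
    junctions = []
    for truth in truths:
        segments.extend(_emit_segments(truth))
        junctions.extend(_emit_junctions(truth))

    depth_rngs = np.random.default_rng(ss_depth).spawn(len(truths))
    depth = {
        t.sample: _emit_depth(t, config, r) for t, r in zip(truths, depth_rngs)
    }

    cohort = CohortTruth(config, truths)
    expression = emit_expression(
        cohort, config.expr_coeffs, config.expr_noise_sd, rng=np.random.default_rng(ss_expr)
    )
    metadata = SampleTable(
        pd.DataFrame(
            {
                "sample": [t.sample for t in truths],
                "tumor_type": [t.tumor_type for t in truths],
                "patient": [t.patient for t in truths],
            }
        )
    )
    return SimResult(segments, junctions, depth, expression, metadata, cohort)


def _emit_segments(truth: SampleTruth) -> list[CopyNumberSegment]:
    """Observed (emitted) segments: the true haplotype profile, except that
    SCNA-dropout deletions leave no trace in the segment table."""
    emitted = truth
    if truth.has_del and not truth.scna_emitted:
        emitted = dataclasses.replace(truth, del_interval=None)
    pieces = _haplotype_profile(emitted)
    segs = []
    # merge adjacent pieces with identical copy state
    merged: list[list] = []
    for s, e, a, b in pieces:
        if merged and (merged[-1][2], merged[-1][3]) == (a, b) and merged[-1][1] == s:
            merged[-1][1] = e
        else:
            merged.append([s, e, a, b])
    for s, e, a, b in merged:
        total = a + b
        minor = min(a, b)
        segs.append(CopyNumberSegment(truth.sample, CHROM, s, e, total, minor))
    return segs


def _emit_junctions(truth: SampleTruth) -> list[SVJunction]:
    out = []
    if truth.amp_interval:
        s, e = truth.amp_interval
        # tandem-duplication-like signature at amplification boundaries
        out.append(
            SVJunction(truth.sample, CHROM, s, "-", CHROM, e, "+", name=f"{truth.sample}_amp")
        )
    if truth.del_interval:
        s, e = truth.del_interval
        out.append(
            SVJunction(truth.sample, CHROM, s, "+", CHROM, e, "-", name=f"{truth.sample}_del")
        )
    return out


def _emit_depth(truth: SampleTruth, config: SimConfig, rng: np.random.Generator) -> ReadDepthTrack:
    region_start, region_end = config.depth_region
    starts = np.arange(region_start, region_end, config.bin_size, dtype=np.int64)
    ends = np.minimum(starts + config.bin_size, region_end)
    pieces = _haplotype_profile(truth)
    cn = np.full(len(starts), 2.0)
    for s, e, a, b in pieces:
        mask = (starts < e) & (ends > s)
        # bin assigned the copy state of the piece covering its start
        mask &= (starts >= s)
        cn[mask] = a + b
    cn_eff = config.purity * cn + (1 - config.purity) * 2.0
    mean_counts = config.coverage * cn_eff / 2.0
    if np.isinf(config.depth_dispersion):
        counts = rng.poisson(mean_counts)
    else:
        size = config.depth_dispersion
        # NB parameterized by size and mean; p = size / (size + mean)
        p = size / (size + np.maximum(mean_counts, 1e-12))
        counts = np.where(mean_counts > 0, rng.negative_binomial(size, p), 0)
    ratios = counts / config.coverage
    return ReadDepthTrack(truth.sample, CHROM, starts, ends, ratios)


def emit_expression(
    truth: CohortTruth,
    coeffs: ExpressionModelCoeffs,
    noise_sd: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ExpressionTable:
    """Per-sample FPKM = max(0, linear predictor + Gaussian noise).

    Emits a gene-level row for each of the three loci plus isoform rows
    for the target gene (long, short-a, short-b transcripts; short-b far
    below short-a). Neighbor and driver genes follow simple dosage models
    so that co-expression structure exists without extra knobs.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    samples = [t.sample for t in truth.samples]
    n = len(samples)

    target = np.empty(n)
    neighbor = np.empty(n)
    driver = np.empty(n)
    for i, t in enumerate(truth.samples):
        mu = coeffs.linear_predictor(t.tumor_type, t.target_locus_cn, t.has_del)
        target[i] = max(0.0, mu + rng.normal(0.0, noise_sd))
        neighbor[i] = max(0.0, 5.0 + 1.5 * t.neighbor_locus_cn + rng.normal(0.0, noise_sd))
        driver[i] = max(0.0, 4.0 + 2.5 * t.driver_locus_cn + rng.normal(0.0, noise_sd))

    rows = {
        TARGET_LOCUS.name: target,
        f"{TARGET_LOCUS.name}-long": ISOFORM_FRACTIONS["long"] * target,
        f"{TARGET_LOCUS.name}-short_a": ISOFORM_FRACTIONS["short_a"] * target,
        f"{TARGET_LOCUS.name}-short_b": ISOFORM_FRACTIONS["short_b"] * target,
        NEIGHBOR_LOCUS.name: neighbor,
        DRIVER_LOCUS.name: driver,
    }
    df = pd.DataFrame(rows, index=samples).T
    return ExpressionTable(df)


# --- gene-matrix generator for differential-expression calibration ----------


def simulate_de_matrix(
    n_genes: int = 2000,
    n_planted: int = 20,
    fold_change: float = 4.0,
    n_carriers: int = 20,
    n_noncarriers: int = 180,
    noise_sd_log2: float = 0.25,
    tumor_types: tuple[str, ...] = TUMOR_TYPES,
    seed: int = 0,
):
    """Expression matrix with planted carrier-specific fold changes.

    Genes are log2-normal around per-gene baselines with additive
    tumor-type offsets; ``n_planted`` genes add log2(fold_change) in
    carriers. Returns (ExpressionTable, carrier flags, tumor types,
    planted gene ids).
    """
    rng = np.random.default_rng(seed)
    n = n_carriers + n_noncarriers
    samples = [f"S{i + 1:04d}" for i in range(n)]
    carrier = pd.Series([True] * n_carriers + [False] * n_noncarriers, index=samples)
    ttype = pd.Series(rng.choice(tumor_types, size=n), index=samples)

    base = rng.uniform(3.0, 8.0, size=n_genes)
    type_offsets = {t: rng.normal(0.0, 0.5, size=n_genes) for t in tumor_types}
    log2expr = np.empty((n_genes, n))
    for j, s in enumerate(samples):
        log2expr[:, j] = base + type_offsets[ttype[s]] + rng.normal(0.0, noise_sd_log2, n_genes)
    planted = [f"G{g + 1:05d}" for g in range(n_planted)]
    log2expr[:n_planted, :n_carriers] += np.log2(fold_change)

    genes = [f"G{g + 1:05d}" for g in range(n_genes)]
    fpkm = np.clip(np.exp2(log2expr) - 1.0, 0.0, None)
    table = ExpressionTable(pd.DataFrame(fpkm, index=genes, columns=samples))
    return table, carrier, ttype, planted
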