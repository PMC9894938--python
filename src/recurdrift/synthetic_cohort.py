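"""Synthetic paired primary/recurrence cohort with known ground truth.

Emulates the statistical structure of a paired tumor-evolution study — 27
primary breast tumors each matched by an in-breast recurrence — without any
patient data:

* paired variant tables share clonal variants (present in both members,
  alt support ~ Binomial(depth, purity * CCF / 2)) and diverge by private
  variants; trinucleotide contexts are drawn from each sample's signature
  mixture applied to a reference signature matrix;
* germline contaminants carry a nonzero population allele frequency and
  recurrent artifacts are planted in at least two simulated normal samples,
  so the filter cascade has realistic work to do;
* per-sample coverage in fixed 10-kb bins follows a GC-bias curve with
  injected copy-number steps;
* paired expression/protein matrices diverge by per-feature Gaussian noise
  whose scale (``drift_sigma``) controls the expected cosine drift, plus a
  receptor-status group effect;
* a clinical table draws biomarker status and follow-up with frequencies
  matching a recurrence cohort.

The genome is a small synthetic one (two chromosomes named chrA/chrB, 10
and 8 Mb); coordinates never pretend to be a real reference build.  Every
variant's strand representation (half are emitted purine-centered, to
exercise pyrimidine normalization downstream) is fixed at the site level,
so a shared variant carries the identical (chrom, pos, ref, alt) key in
both members of a pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .copy_number import CopyNumberError, CoverageBin
from .mutational_signatures import COMPLEMENT, CONTEXT_LABELS, SignatureMatrix

DEFAULT_CHROM_LENGTHS = {"chrA": 10_000_000, "chrB": 8_000_000}
BIN_WIDTH = 10_000

SOMATIC_CONSEQUENCES = (
    ("missense_variant", "MODERATE", 0.70),
    ("stop_gained", "HIGH", 0.10),
    ("synonymous_variant", "LOW", 0.15),
    ("5_prime_UTR_variant", "MODIFIER", 0.05),
)

VARIANT_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "alt_support_tumor",
    "depth_tumor",
    "pop_af_gnomad",
    "pop_af_swefreq",
    "context5",
    "context3",
    "gene",
    "impact",
    "consequence",
)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class CNEvent:
    """One injected copy-number step, applying to PT, IBTR, or both."""

    chrom: str
    start: int
    end: int
    log2_shift: float
    target: str  # PT | IBTR | both

    def __post_init__(self) -> None:
        if self.target not in ("PT", "IBTR", "both"):
            raise ConfigurationError(f"CN event target must be PT/IBTR/both, got {self.target!r}")
        if self.end <= self.start:
            raise ConfigurationError("empty CN event interval")


@dataclass
class CohortConfig:
    """Study conditions for one simulated paired cohort.

    Defaults emulate a 27-pair recurrence cohort: moderate purity, ~30x
    depth, a few hundred clonal variants per pair with more private
    variants gained in the recurrence than lost from the primary, a
    sprinkling of germline contaminants and recurrent artifacts, and one
    recurrence-only gain and one loss on the synthetic genome.
    """

    n_patients: int = 27
    purity_range: tuple[float, float] = (0.3, 0.9)
    depth_mean: float = 30.0
    n_shared_variants: int = 300
    n_private_pt: int = 60
    n_private_ibtr: int = 100
    signature_mix_pt: Sequence[float] = ()
    signature_mix_ibtr: Sequence[float] = ()
    cn_events: Sequence[CNEvent] = field(
        default_factory=lambda: [
            CNEvent("chrA", 2_000_000, 3_000_000, 1.0, "IBTR"),
            CNEvent("chrB", 1_000_000, 1_600_000, -1.0, "IBTR"),
        ]
    )
    drift_sigma: float = 0.5
    germline_af_fraction: float = 0.10
    pon_artifact_fraction: float = 0.05
    seed: int = 0
    chrom_lengths: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    n_rna_features: int = 12_750
    n_protein_features: int = 4_640
    n_normals: int = 5
    bin_noise_sd_frac: float = 0.05
    bin_depth_mean: float = 100.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("cohort must contain at least one patient")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError(f"purity range {self.purity_range} outside (0, 1]")
        if self.depth_mean <= 0 or self.bin_depth_mean <= 0:
            raise ConfigurationError("depth_mean must be positive")
        for n in (self.n_shared_variants, self.n_private_pt, self.n_private_ibtr):
            if n < 0:
                raise ConfigurationError("variant counts must be nonnegative")
        for frac in (self.germline_af_fraction, self.pon_artifact_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError("fractions must lie in [0, 1]")
        if self.drift_sigma < 0:
            raise ConfigurationError("drift_sigma must be nonnegative")
        for name in ("signature_mix_pt", "signature_mix_ibtr"):
            mix = np.asarray(getattr(self, name), dtype=float)
            if mix.size:
                if (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
                    raise ConfigurationError(f"{name} must be a nonnegative simplex vector")


@dataclass
class TruthSet:
    """Ground truth emitted alongside the bundle, keyed by emitted sample ids."""

    signature_fractions: dict[str, np.ndarray]
    cn_events: list[CNEvent]
    expected_gene_calls: dict[str, str]  # gene -> gain | loss
    shared_keys: dict[str, set]
    private_pt_keys: dict[str, set]
    private_ibtr_keys: dict[str, set]
    drift_order: list[str]  # patients, ascending realized expression drift


@dataclass
class CohortBundle:
    """Everything the downstream pipeline reads, in memory."""

    variant_tables: dict[str, pd.DataFrame]  # sample id -> variant TSV dialect
    purity: pd.DataFrame  # sample_id, purity
    coverage_bins: dict[str, list[CoverageBin]]
    expression: pd.DataFrame  # features x samples
    protein: pd.DataFrame
    clinical: pd.DataFrame
    normal_variant_sets: list[set]
    gene_exons: dict[str, list[tuple[str, int, int]]]

    @property
    def pairs(self) -> dict[str, tuple[str, str]]:
        patients = sorted({s.rsplit("_", 1)[0] for s in self.variant_tables})
        return {p: (f"{p}_PT", f"{p}_IBTR") for p in patients}


def synthetic_gene_exons(
    chrom_lengths: Mapping[str, int], spacing: int = 100_000
) -> dict[str, list[tuple[str, int, int]]]:
    """A regular synthetic gene annotation: one gene per ``spacing`` window.

    Each gene gets two 2-kb exons near the window ends, so a 1-Mb event
    covers exactly ten spacing-aligned genes at the defaults.
    """
    exons: dict[str, list[tuple[str, int, int]]] = {}
    i = 0
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        for start in range(0, length - spacing + 1, spacing):
            gene = f"G{i:04d}"
            exons[gene] = [
                (chrom, start + 10_000, start + 12_000),
                (chrom, start + spacing - 12_000, start + spacing - 10_000),
            ]
            i += 1
    return exons


def simulate_coverage_bins(
    cn_profile: Sequence[CNEvent],
    gc_bias_curve: Optional[Callable[[np.ndarray], np.ndarray]],
    depth_mean: float,
    seed,
    chrom_lengths: Mapping[str, int] = DEFAULT_CHROM_LENGTHS,
    gc: Optional[np.ndarray] = None,
    noise_sd_frac: float = 0.05,
    bin_width: int = BIN_WIDTH,
) -> list[CoverageBin]:
    """Tile the genome in fixed-width bins and draw GC-biased coverage.

    Expected coverage of a bin is depth_mean * gc_bias_curve(gc) *
    2**(sum of overlapping log2 shifts); Gaussian noise with sd
    ``noise_sd_frac`` of the expectation is added (clipped at 0).  ``gc``
    fixes the genome's GC track so several samples can share it; otherwise
    it is drawn Beta(20, 20) per bin from ``seed``.
    """
    rng = np.random.default_rng(seed)
    _check_no_overlap(cn_profile)
    rows: list[tuple[str, int, int]] = []
    for chrom in sorted(chrom_lengths):
        for start in range(0, chrom_lengths[chrom] - bin_width + 1, bin_width):
            rows.append((chrom, start, start + bin_width))
    n = len(rows)
    if gc is None:
        gc = rng.beta(20, 20, size=n)
    gc = np.clip(np.asarray(gc, dtype=float), 0.0, 1.0)
    if gc.shape != (n,):
        raise ConfigurationError(f"gc track must have one value per bin ({n})")
    log2cn = np.zeros(n)
    for ev in cn_profile:
        for i, (chrom, start, end) in enumerate(rows):
            if chrom == ev.chrom and start < ev.end and ev.start < end:
                log2cn[i] += ev.log2_shift
    bias = gc_bias_curve(gc) if gc_bias_curve is not None else np.ones(n)
    expected = depth_mean * np.asarray(bias, dtype=float) * 2.0**log2cn
    if noise_sd_frac > 0:
        expected = expected + rng.normal(0.0, noise_sd_frac * np.maximum(expected, 1e-12))
    coverage = np.maximum(expected, 0.0)
    return [
        CoverageBin(chrom, start, end, float(g), float(c))
        for (chrom, start, end), g, c in zip(rows, gc, coverage)
    ]


def _check_no_overlap(events: Sequence[CNEvent]) -> None:
    by_chrom: dict[str, list[CNEvent]] = {}
    for ev in events:
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom, evs in by_chrom.items():
        evs = sorted(evs, key=lambda e: e.start)
        for a, b in zip(evs[:-1], evs[1:]):
            if b.start < a.end and {a.target, b.target} != {"PT", "IBTR"}:
                raise CopyNumberError(f"overlapping CN events on {chrom}")


@dataclass(frozen=True)
class _VariantDef:
    """Sample-independent description of one simulated variant site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    context5: str
    context3: str
    gene: str
    impact: str
    consequence: str
    pop_af: Optional[float]  # None or 0 for somatic, positive for germline

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def _make_variant_defs(
    rng: np.random.Generator,
    positions: Sequence[tuple[str, int]],
    p96: np.ndarray,
    gene_list: Sequence[str],
    pop_afs: Sequence[Optional[float]],
) -> list[_VariantDef]:
    """Fix each site's substitution, strand representation, and annotation.

    The pyrimidine-centered context is drawn from the sample group's
    96-context probability vector; half the sites are then re-expressed on
    the purine strand, which downstream classification must undo.
    """
    terms = [c for c, _, _ in SOMATIC_CONSEQUENCES]
    probs = [w for _, _, w in SOMATIC_CONSEQUENCES]
    impact_of = {c: i for c, i, _ in SOMATIC_CONSEQUENCES}
    ctx_idx = rng.choice(96, size=len(positions), p=p96)
    genes = rng.integers(0, len(gene_list), size=len(positions))
    cons = rng.choice(len(terms), size=len(positions), p=probs)
    flips = rng.random(len(positions)) < 0.5
    defs: list[_VariantDef] = []
    for (chrom, pos), ci, gi, co, flip, af in zip(positions, ctx_idx, genes, cons, flips, pop_afs):
        label = CONTEXT_LABELS[ci]  # e.g. "A[C>T]G"
        flank5, ref, alt, flank3 = label[0], label[2], label[4], label[6]
        if flip:
            ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
            flank5, flank3 = COMPLEMENT[flank3], COMPLEMENT[flank5]
        defs.append(
            _VariantDef(
                chrom, pos, ref, alt, flank5, flank3,
                gene_list[gi], impact_of[terms[co]], terms[co], af,
            )
        )
    return defs


def _draw_sample_rows(
    rng: np.random.Generator,
    defs: Sequence[_VariantDef],
    depth_mean: float,
    vaf: float,
) -> list[dict]:
    """Observe a set of variant sites in one sample: depth and alt support."""
    rows = []
    for d in defs:
        depth = max(int(rng.poisson(depth_mean)), 1)
        support = int(rng.binomial(depth, vaf))
        rows.append(
            {
                "chrom": d.chrom,
                "pos": d.pos,
                "ref": d.ref,
                "alt": d.alt,
                "alt_support_tumor": support,
                "depth_tumor": depth,
                "pop_af_gnomad": d.pop_af,
                "pop_af_swefreq": 0.0 if d.pop_af is None else d.pop_af,
                "context5": d.context5,
                "context3": d.context3,
                "gene": d.gene,
                "impact": d.impact,
                "consequence": d.consequence,
            }
        )
    return rows


def simulate_cohort(
    config: CohortConfig, signatures: SignatureMatrix
) -> tuple[CohortBundle, TruthSet]:
    """Generate the full paired cohort bundle plus its ground truth.

    Deterministic for a fixed config: every random draw flows from
    per-patient substreams seeded as (config.seed, patient index), so
    adding patients does not perturb earlier ones.
    """
    mix_pt = np.asarray(config.signature_mix_pt, dtype=float)
    mix_ibtr = np.asarray(config.signature_mix_ibtr, dtype=float)
    if mix_pt.size == 0:
        mix_pt = np.full(signatures.k, 1.0 / signatures.k)
    if mix_ibtr.size == 0:
        mix_ibtr = np.full(signatures.k, 1.0 / signatures.k)
    if mix_pt.size != signatures.k or mix_ibtr.size != signatures.k:
        raise ConfigurationError("signature mixture length must match the signature matrix")

    genome_rng = np.random.default_rng([config.seed, 999_983])
    n_bins = sum(len(range(0, L - BIN_WIDTH + 1, BIN_WIDTH)) for L in config.chrom_lengths.values())
    gc_track = genome_rng.beta(20, 20, size=n_bins)
    gc_curve = lambda g: 0.5 + np.sin(np.pi * np.clip(g, 0, 1)) ** 2  # noqa: E731

    gene_exons = synthetic_gene_exons(config.chrom_lengths)
    gene_list = sorted(gene_exons)
    p96_pt = signatures.profiles @ mix_pt
    p96_ibtr = signatures.profiles @ mix_ibtr
    p96_pt = p96_pt / p96_pt.sum()
    p96_ibtr = p96_ibtr / p96_ibtr.sum()

    # recurrent artifacts: one cohort-wide set, each planted in two normals
    artifact_rng = np.random.default_rng([config.seed, 424_243])
    n_artifacts = round(config.pon_artifact_fraction * config.n_shared_variants)
    artifact_defs = _make_variant_defs(
        artifact_rng,
        _unique_positions(artifact_rng, n_artifacts, config.chrom_lengths),
        p96_pt,
        gene_list,
        [None] * n_artifacts,
    )
    normal_sets: list[set] = [set() for _ in range(config.n_normals)]
    for d in artifact_defs:
        for h in artifact_rng.choice(config.n_normals, size=2, replace=False):
            normal_sets[h].add(d.key)

    variant_tables: dict[str, pd.DataFrame] = {}
    purity_rows = []
    coverage: dict[str, list[CoverageBin]] = {}
    clinical_rows = []
    truth_sig: dict[str, np.ndarray] = {}
    shared_keys: dict[str, set] = {}
    private_pt: dict[str, set] = {}
    private_ibtr: dict[str, set] = {}
    drift_norms: dict[str, float] = {}

    rna = np.zeros((config.n_rna_features, 2 * config.n_patients))
    prot = np.zeros((config.n_protein_features, 2 * config.n_patients))
    sample_ids: list[str] = []
    base_rng = np.random.default_rng([config.seed, 77])
    rna_mu = base_rng.normal(8.0, 2.0, size=config.n_rna_features)
    prot_mu = base_rng.normal(20.0, 2.0, size=config.n_protein_features)
    er_effect_rna = base_rng.random(config.n_rna_features) < 0.05
    er_effect_prot = base_rng.random(config.n_protein_features) < 0.05

    pt_events = [e for e in config.cn_events if e.target in ("PT", "both")]
    ibtr_events = [e for e in config.cn_events if e.target in ("IBTR", "both")]

    # shared (clonal) variants carry the ancestral PT-mixture contexts, so a
    # recurrence sample's aggregate spectrum follows the count-weighted blend
    n_som_ibtr = config.n_shared_variants + config.n_private_ibtr
    if n_som_ibtr > 0:
        mix_ibtr_sample = (
            config.n_shared_variants * mix_pt + config.n_private_ibtr * mix_ibtr
        ) / n_som_ibtr
    else:
        mix_ibtr_sample = mix_ibtr

    for p in range(config.n_patients):
        rng = np.random.default_rng([config.seed, p])
        patient = f"P{p:02d}"
        pt_id, ibtr_id = f"{patient}_PT", f"{patient}_IBTR"
        sample_ids += [pt_id, ibtr_id]
        pur_pt = float(rng.uniform(*config.purity_range))
        pur_ibtr = float(rng.uniform(*config.purity_range))
        purity_rows += [
            {"sample_id": pt_id, "purity": pur_pt},
            {"sample_id": ibtr_id, "purity": pur_ibtr},
        ]

        n_total = config.n_shared_variants + config.n_private_pt + config.n_private_ibtr
        n_germ = round(config.germline_af_fraction * n_total)
        positions = _unique_positions(rng, n_total + n_germ, config.chrom_lengths)
        cut1 = config.n_shared_variants
        cut2 = cut1 + config.n_private_pt
        cut3 = cut2 + config.n_private_ibtr
        shared_defs = _make_variant_defs(rng, positions[:cut1], p96_pt, gene_list, [0.0 if i % 2 else None for i in range(cut1)])
        pt_defs = _make_variant_defs(rng, positions[cut1:cut2], p96_pt, gene_list, [None] * (cut2 - cut1))
        ibtr_defs = _make_variant_defs(rng, positions[cut2:cut3], p96_ibtr, gene_list, [None] * (cut3 - cut2))
        germ_afs = [float(a) for a in rng.uniform(0.01, 0.5, size=n_germ)]
        germ_defs = _make_variant_defs(rng, positions[cut3:], p96_pt, gene_list, germ_afs)

        shared_keys[patient] = {d.key for d in shared_defs}
        private_pt[patient] = {d.key for d in pt_defs}
        private_ibtr[patient] = {d.key for d in ibtr_defs}

        rows_pt = (
            _draw_sample_rows(rng, shared_defs, config.depth_mean, pur_pt / 2.0)
            + _draw_sample_rows(rng, pt_defs, config.depth_mean, pur_pt / 2.0)
            + _draw_sample_rows(rng, germ_defs, config.depth_mean, 0.5)
            + _draw_sample_rows(rng, artifact_defs, config.depth_mean, 0.3)
        )
        rows_ibtr = (
            _draw_sample_rows(rng, shared_defs, config.depth_mean, pur_ibtr / 2.0)
            + _draw_sample_rows(rng, ibtr_defs, config.depth_mean, pur_ibtr / 2.0)
            + _draw_sample_rows(rng, germ_defs, config.depth_mean, 0.5)
            + _draw_sample_rows(rng, artifact_defs, config.depth_mean, 0.3)
        )
        variant_tables[pt_id] = pd.DataFrame(rows_pt, columns=list(VARIANT_COLUMNS))
        variant_tables[ibtr_id] = pd.DataFrame(rows_ibtr, columns=list(VARIANT_COLUMNS))
        truth_sig[pt_id] = mix_pt.copy()
        truth_sig[ibtr_id] = mix_ibtr_sample.copy()

        coverage[pt_id] = simulate_coverage_bins(
            pt_events, gc_curve, config.bin_depth_mean, [config.seed, p, 1],
            config.chrom_lengths, gc_track, config.bin_noise_sd_frac,
        )
        coverage[ibtr_id] = simulate_coverage_bins(
            ibtr_events, gc_curve, config.bin_depth_mean, [config.seed, p, 2],
            config.chrom_lengths, gc_track, config.bin_noise_sd_frac,
        )

        col = 2 * p
        er = "positive" if rng.random() < 0.65 else "negative"
        rna_base = rna_mu + rng.normal(0, 1.0, size=config.n_rna_features)
        prot_base = prot_mu + rng.normal(0, 1.0, size=config.n_protein_features)
        if er == "negative":
            rna_base = rna_base + 0.5 * er_effect_rna
            prot_base = prot_base + 0.5 * er_effect_prot
        if config.drift_sigma > 0:
            rna_noise = rng.normal(0, config.drift_sigma, size=config.n_rna_features)
            prot_noise = rng.normal(0, config.drift_sigma, size=config.n_protein_features)
        else:
            rna_noise = np.zeros(config.n_rna_features)
            prot_noise = np.zeros(config.n_protein_features)
        rna[:, col] = rna_base
        rna[:, col + 1] = rna_base + rna_noise
        prot[:, col] = prot_base
        prot[:, col + 1] = prot_base + prot_noise
        drift_norms[patient] = float(np.linalg.norm(rna_noise))

        pgr = "positive" if rng.random() < 0.45 else "negative"
        ki67_pt = "high" if rng.random() < 0.55 else "low"
        ki67_ibtr = ki67_pt if rng.random() > 0.26 else ("low" if ki67_pt == "high" else "high")
        pgr_ibtr = pgr if rng.random() > 0.22 else ("negative" if pgr == "positive" else "positive")
        erbb2 = "amplified" if rng.random() < 0.18 else "normal"
        grade = ["low", "intermediate", "high"][int(rng.choice(3, p=[0.03, 0.6, 0.37]))]
        age = ">55" if rng.random() < 0.52 else "<=55"
        time_months = float(np.exp(rng.normal(3.3, 0.6)))
        for role, ki, pg in (("PT", ki67_pt, pgr), ("IBTR", ki67_ibtr, pgr_ibtr)):
            clinical_rows.append(
                {
                    "patient_id": patient,
                    "role": role,
                    "ER": er,
                    "PgR": pg,
                    "Ki67": ki,
                    "ERBB2": erbb2,
                    "grade": grade,
                    "age_group": age,
                    "ibtrfs_time_months": round(time_months, 2),
                    "event": True,
                }
            )

    expected_calls: dict[str, str] = {}
    for gene, exons in gene_exons.items():
        shift = 0.0
        for ev in config.cn_events:
            if ev.target == "both":
                continue
            sign = 1.0 if ev.target == "IBTR" else -1.0
            if any(c == ev.chrom and s < ev.end and ev.start < e for c, s, e in exons):
                shift += sign * ev.log2_shift
        if shift > 0:
            expected_calls[gene] = "gain"
        elif shift < 0:
            expected_calls[gene] = "loss"

    bundle = CohortBundle(
        variant_tables=variant_tables,
        purity=pd.DataFrame(purity_rows),
        coverage_bins=coverage,
        expression=pd.DataFrame(rna, index=[f"T{i:05d}" for i in range(config.n_rna_features)], columns=sample_ids),
        protein=pd.DataFrame(prot, index=[f"Q{i:05d}" for i in range(config.n_protein_features)], columns=sample_ids),
        clinical=pd.DataFrame(clinical_rows),
        normal_variant_sets=normal_sets,
        gene_exons=gene_exons,
    )
    truth = TruthSet(
        signature_fractions=truth_sig,
        cn_events=list(config.cn_events),
        expected_gene_calls=expected_calls,
        shared_keys=shared_keys,
        private_pt_keys=private_pt,
        private_ibtr_keys=private_ibtr,
        drift_order=sorted(drift_norms, key=drift_norms.get),
    )
    return bundle, truth


def _unique_positions(
    rng: np.random.Generator, n: int, chrom_lengths: Mapping[str, int]
) -> list[tuple[str, int]]:
    """Draw n distinct (chrom, pos) sites, length-proportional across chromosomes."""
    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    seen: set[tuple[str, int]] = set()
    out: list[tuple[str, int]] = []
    while len(out) < n:
        c = chroms[int(rng.choice(len(chroms), p=probs))]
        pos = int(rng.integers(1, chrom_lengths[c] + 1))
        if (c, pos) in seen:
            continue
        seen.add((c, pos))
        out.append((c, pos))
    return out


def random_signature_matrix(k: int = 4, seed: int = 0, concentration: float = 0.3) -> SignatureMatrix:
    """A small synthetic signature matrix with well-separated sparse columns."""
    rng = np.random.default_rng(seed)
    profiles = rng.dirichlet(np.full(96, concentration), size=k).T
    return SignatureMatrix([f"SigS{i + 1}" for i in range(k)], profiles)
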