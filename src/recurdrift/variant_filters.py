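"""Ordered somatic-SNV filter cascade for paired tumor analyses.

Whole-genome tumor samples without a matched normal retain abundant germline
polymorphisms and sequencing artifacts among their candidate somatic calls.
The cascade removes these with five filters applied in a fixed order:

1. population allele frequency — the variant must be absent from population
   databases (frequency exactly 0 or missing);
2. allelic depth — at least 2 tumor reads support the alternative allele,
   and at most 1 normal read does when a matched normal exists;
3. coverage — at least 10 reads cover the site in the tumor (and in the
   matched normal when present);
4. panel of normals — the variant key must not recur in the blacklist built
   from the cohort's normal samples;
5. purity-scaled probability ratio — a binomial likelihood comparison of a
   tumor ("cancer") model whose success probability is scaled by the sample's
   tumor-purity estimate against a diploid-germline background model; the
   variant is kept when either the heterozygous or the homozygous cancer
   model is sufficiently more likely than its background counterpart.

Each removal is attributed to the first failing filter, which makes the
per-filter counts interpretable as a waterfall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from scipy.stats import binom

VALID_BASES = frozenset("ACGT")
VALID_IMPACTS = frozenset({"HIGH", "MODERATE", "LOW", "MODIFIER"})

#: consequence terms excluded from the cancer-gene SNV list even when the
#: annotated impact is MODERATE/HIGH
EXCLUDED_CONSEQUENCES = frozenset(
    {
        "downstream_gene_variant",
        "upstream_gene_variant",
        "3_prime_UTR_variant",
        "5_prime_UTR_variant",
        "synonymous_variant",
    }
)

FILTER_ORDER = ("population_af", "allelic_depth", "coverage", "pon", "tpes")


class VariantInputError(ValueError):
    """Raised when a variant record violates a structural invariant."""


@dataclass(frozen=True)
class VariantRecord:
    """One somatic single-nucleotide variant call with its annotations.

    ``alt_support_tumor`` and ``depth_tumor`` are the binomial observation
    (s, c) entering the purity filter.  Population allele frequencies are
    ``None`` when the variant is absent from the database, which is distinct
    from an observed frequency of 0 only in provenance — both pass filter 1.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_support_tumor: int
    depth_tumor: int
    alt_support_normal: Optional[int] = None
    depth_normal: Optional[int] = None
    pop_af_gnomad: Optional[float] = None
    pop_af_swefreq: Optional[float] = None
    context5: Optional[str] = None
    context3: Optional[str] = None
    gene: Optional[str] = None
    impact: Optional[str] = None
    consequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise VariantInputError(
                f"ref/alt must be single A/C/G/T bases, got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise VariantInputError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if not 0 <= self.alt_support_tumor <= self.depth_tumor:
            raise VariantInputError(
                f"tumor support {self.alt_support_tumor} outside [0, depth={self.depth_tumor}]"
            )
        if (self.alt_support_normal is None) != (self.depth_normal is None):
            raise VariantInputError("normal support and depth must be given together")
        if self.alt_support_normal is not None:
            if not 0 <= self.alt_support_normal <= self.depth_normal:  # type: ignore[operator]
                raise VariantInputError("normal support outside [0, normal depth]")
        for af in (self.pop_af_gnomad, self.pop_af_swefreq):
            if af is not None and not 0.0 <= af <= 1.0:
                raise VariantInputError(f"population AF {af} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Variant identity used by the PoN and by paired gain/loss calls."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def has_normal(self) -> bool:
        return self.alt_support_normal is not None


@dataclass(frozen=True)
class PurityEstimate:
    """Tumor-cell fraction t in (0, 1] for one sample; None when no estimate exists."""

    sample_id: str
    purity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.purity is not None and not 0.0 < self.purity <= 1.0:
            raise VariantInputError(f"purity {self.purity} outside (0, 1]")


class PanelOfNormals:
    """Blacklist of variant keys recurring across the cohort's normal samples."""

    def __init__(self, keys: Iterable[tuple[str, int, str, str]]):
        self._keys = frozenset(keys)

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self._keys

    def __len__(self) -> int:
        return len(self._keys)

    def __iter__(self):
        return iter(self._keys)


@dataclass(frozen=True)
class TpesEvaluation:
    """Both binomial model comparisons for one variant under one purity.

    ``log2_ratio_het``/``log2_ratio_hom`` may be -inf (numerator underflows to
    zero probability) or ``None`` (background probability exactly zero, the
    model is non-informative and excluded from the keep decision).
    """

    p_cancer_het: float
    p_background_het: float
    p_cancer_hom: float
    p_background_hom: float
    log2_ratio_het: Optional[float]
    log2_ratio_hom: Optional[float]
    keep: bool


@dataclass
class FilterReport:
    """Waterfall of removals attributed to the first failing filter."""

    input_count: int = 0
    removed: dict[str, int] = field(default_factory=lambda: {f: 0 for f in FILTER_ORDER})
    surviving: int = 0

    def check(self) -> None:
        if self.input_count - sum(self.removed.values()) != self.surviving:
            raise AssertionError("filter report does not balance")


def build_panel_of_normals(
    normal_variant_sets: Sequence[Iterable[tuple[str, int, str, str]]],
) -> PanelOfNormals:
    """Collect variant keys observed in at least two distinct normal samples."""
    if len(normal_variant_sets) == 0:
        raise VariantInputError("panel of normals requires at least one normal sample")
    counts: dict[tuple[str, int, str, str], int] = {}
    for sample in normal_variant_sets:
        for key in set(sample):  # set() so one sample counts once per key
            counts[key] = counts.get(key, 0) + 1
    return PanelOfNormals(k for k, n in counts.items() if n >= 2)


def population_af_pass(v: VariantRecord) -> bool:
    """True when the variant is unseen in both population databases (AF 0 or missing)."""
    for af in (v.pop_af_gnomad, v.pop_af_swefreq):
        if af is not None and af != 0.0:
            return False
    return True


def allelic_depth_pass(v: VariantRecord) -> bool:
    """Tumor alt support >= 2; matched-normal alt support <= 1 when available."""
    if v.alt_support_tumor < 2:
        return False
    if v.has_normal and v.alt_support_normal > 1:  # type: ignore[operator]
        return False
    return True


def coverage_pass(v: VariantRecord) -> bool:
    """Tumor depth >= 10; matched-normal depth >= 10 when available."""
    if v.depth_tumor < 10:
        return False
    if v.has_normal and v.depth_normal < 10:  # type: ignore[operator]
        return False
    return True


def pon_pass(v: VariantRecord, pon: PanelOfNormals) -> bool:
    """True when the (chrom, pos, ref, alt) key is absent from the panel of normals."""
    return v.key not in pon


def tpes_log2_ratio(s: int, c: int, p_cancer: float, p_background: float) -> Optional[float]:
    """log2 of twice the binomial-pmf ratio of the cancer vs background model.

    Returns the ratio computed in log space (log-gamma pmf, stable at high
    depth), ``-inf`` when the cancer-model pmf is zero while the background
    pmf is positive, and ``None`` (undefined) when the background pmf is
    zero.
    """
    if not 0 <= s <= c:
        raise VariantInputError(f"support {s} outside [0, coverage={c}]")
    if not (0.0 <= p_cancer <= 1.0 and 0.0 <= p_background <= 1.0):
        raise VariantInputError("model probabilities must lie in [0, 1]")
    log_num = binom.logpmf(s, c, p_cancer)
    log_den = binom.logpmf(s, c, p_background)
    if math.isinf(log_den):  # background probability 0 -> ratio undefined
        return None
    if math.isinf(log_num):
        return -math.inf
    # log2(2 * num/den) = 1 + (ln num - ln den)/ln 2
    return 1.0 + (log_num - log_den) / math.log(2)


def evaluate_tpes(v: VariantRecord, purity: PurityEstimate, threshold: float = -1.0) -> TpesEvaluation:
    """Evaluate heterozygous and homozygous purity-scaled models for one variant.

    The heterozygous cancer model has success probability 0.5*t against a 0.5
    background; the homozygous model uses t against 1.0.  The variant is kept
    when any defined model's log2 ratio exceeds ``threshold``.  A model whose
    background pmf is exactly zero is non-informative and excluded from the
    disjunction; if every model is non-informative the variant is kept.
    """
    t = purity.purity
    if t is None:
        raise VariantInputError("evaluate_tpes requires a purity estimate; use tpes_pass")
    p_het_c, p_het_b = 0.5 * t, 0.5
    p_hom_c, p_hom_b = t, 1.0
    r_het = tpes_log2_ratio(v.alt_support_tumor, v.depth_tumor, p_het_c, p_het_b)
    r_hom = tpes_log2_ratio(v.alt_support_tumor, v.depth_tumor, p_hom_c, p_hom_b)
    defined = [r for r in (r_het, r_hom) if r is not None]
    keep = True if not defined else any(r > threshold for r in defined)
    return TpesEvaluation(p_het_c, p_het_b, p_hom_c, p_hom_b, r_het, r_hom, keep)


def tpes_pass(v: VariantRecord, purity: PurityEstimate, threshold: float = -1.0) -> bool:
    """Purity filter keep decision; skipped (always True) without a purity estimate."""
    if purity.purity is None:
        return True
    return evaluate_tpes(v, purity, threshold).keep


def apply_cascade(
    variants: Sequence[VariantRecord],
    purity: PurityEstimate,
    pon: PanelOfNormals,
    threshold: float = -1.0,
) -> tuple[list[VariantRecord], FilterReport]:
    """Run the five filters in order on one sample's variants.

    Returns the surviving records and a report attributing each removal to
    the first failing filter.  The kept set is order-invariant (it is the
    conjunction of the individual filters); only the attribution depends on
    the order.
    """
    report = FilterReport(input_count=len(variants))
    kept: list[VariantRecord] = []
    for v in variants:
        if not population_af_pass(v):
            report.removed["population_af"] += 1
        elif not allelic_depth_pass(v):
            report.removed["allelic_depth"] += 1
        elif not coverage_pass(v):
            report.removed["coverage"] += 1
        elif not pon_pass(v, pon):
            report.removed["pon"] += 1
        elif not tpes_pass(v, purity, threshold):
            report.removed["tpes"] += 1
        else:
            kept.append(v)
    report.surviving = len(kept)
    report.check()
    return kept, report


def consequence_pass(v: VariantRecord) -> bool:
    """Restrict to MODERATE/HIGH impact, excluding UTR/up-/downstream/synonymous terms."""
    if v.impact is None or v.impact not in VALID_IMPACTS:
        raise VariantInputError(f"unknown impact label {v.impact!r}")
    if v.impact not in ("MODERATE", "HIGH"):
        return False
    if v.consequence is not None and _normalize_consequence(v.consequence) in EXCLUDED_CONSEQUENCES:
        return False
    return True


def _normalize_consequence(term: str) -> str:
    return (
        term.strip()
        .lower()
        .replace("'", "_prime_")
        .replace("′", "_prime_")  # typographic prime
        .replace(" ", "_")
        .replace("__", "_")
        .replace("3_prime_utr", "3_prime_UTR")
        .replace("5_prime_utr", "5_prime_UTR")
    )


def snv_gain_loss(
    pt_kept: Iterable[tuple[str, int, str, str]],
    ibtr_kept: Iterable[tuple[str, int, str, str]],
) -> tuple[set, set, set]:
    """Paired variant turnover: (gained in recurrence, lost from primary, shared)."""
    pt, ibtr = set(pt_kept), set(ibtr_kept)
    return ibtr - pt, pt - ibtr, pt & ibtr
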