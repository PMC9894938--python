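"""96-context mutational spectra and reference-signature refitting.

A sample's single-nucleotide variants are classified into the 96
pyrimidine-centered trinucleotide substitution contexts (6 substitution
classes x 4 5' flanks x 4 3' flanks).  The resulting count spectrum is
modeled as a nonnegative linear combination of reference signature profiles
(COSMIC v2 layout: 96 labeled rows, one column per signature) and refit by
non-negative least squares; contributions are reported as fractions of the
fitted weight.  Per-patient evolution of mutational processes is then the
fractional contribution delta between the recurrence and its matched
primary, and signatures are short-listed by their mean contribution across
the cohort (top two quartiles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

#: canonical ordering of the 96 contexts: substitution class major, then
#: 5' flank, then 3' flank — the COSMIC v2 row layout
CONTEXT_LABELS = tuple(
    f"{f5}[{sub}]{f3}" for sub in SUBSTITUTION_CLASSES for f5 in BASES for f3 in BASES
)
CONTEXT_INDEX = {label: i for i, label in enumerate(CONTEXT_LABELS)}


class SignatureError(ValueError):
    pass


@dataclass(frozen=True)
class MutationContext:
    """A pyrimidine-centered trinucleotide substitution context."""

    substitution: str
    flank5: str
    flank3: str

    def __post_init__(self) -> None:
        if self.substitution not in SUBSTITUTION_CLASSES:
            raise SignatureError(f"not a pyrimidine-centered class: {self.substitution!r}")
        if self.flank5 not in BASES or self.flank3 not in BASES:
            raise SignatureError(f"ambiguous flanking base {self.flank5!r}/{self.flank3!r}")

    @property
    def label(self) -> str:
        return f"{self.flank5}[{self.substitution}]{self.flank3}"

    @property
    def index(self) -> int:
        return CONTEXT_INDEX[self.label]


def classify_context(ref: str, alt: str, flank5: str, flank3: str) -> MutationContext:
    """Map a substitution with flanks onto its pyrimidine-centered context.

    When the reference base is a purine the substitution is re-expressed on
    the opposite strand: ref/alt are complemented and the flanks swap and
    complement, so both strand representations of a mutation land in the
    same one of the 96 classes.
    """
    for b in (ref, alt, flank5, flank3):
        if b not in COMPLEMENT:
            raise SignatureError(f"ambiguous base {b!r}")
    if ref == alt:
        raise SignatureError("ref and alt are identical")
    if ref in ("G", "A"):
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        flank5, flank3 = COMPLEMENT[flank3], COMPLEMENT[flank5]
    return MutationContext(f"{ref}>{alt}", flank5, flank3)


@dataclass
class Spectrum96:
    """Counts over the 96 contexts for one sample, plus unclassifiable records."""

    sample_id: str
    counts: np.ndarray
    errors: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise SignatureError("a spectrum has exactly 96 context counts")
        if (self.counts < 0).any():
            raise SignatureError("negative context count")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CONTEXT_LABELS), name=self.sample_id)


def build_spectrum(variants: Sequence, sample_id: str = "") -> Spectrum96:
    """Tally classified variants into a 96-context spectrum.

    Records lacking flanking bases, or with ambiguous bases, are reported in
    ``errors`` rather than silently dropped; classified counts always sum to
    the number of classifiable inputs.
    """
    counts = np.zeros(96)
    errors: list[str] = []
    for v in variants:
        if v.context5 is None or v.context3 is None:
            errors.append(f"{v.chrom}:{v.pos} {v.ref}>{v.alt}: missing flanking bases")
            continue
        try:
            ctx = classify_context(v.ref, v.alt, v.context5, v.context3)
        except SignatureError as exc:
            errors.append(f"{v.chrom}:{v.pos} {v.ref}>{v.alt}: {exc}")
            continue
        counts[ctx.index] += 1
    return Spectrum96(sample_id, counts, errors)


class SignatureMatrix:
    """Reference signature profiles: 96 contexts x K signatures, columns on the simplex."""

    def __init__(self, names: Sequence[str], profiles: np.ndarray):
        profiles = np.asarray(profiles, dtype=float)
        if profiles.shape != (96, len(names)):
            raise SignatureError(
                f"profiles must be 96 x {len(names)}, got {profiles.shape}"
            )
        if (profiles < 0).any():
            raise SignatureError("signature profiles must be nonnegative")
        colsums = profiles.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise SignatureError("each signature profile must sum to 1 (within 1e-6)")
        self.names = list(names)
        self.profiles = profiles

    @property
    def k(self) -> int:
        return len(self.names)

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        """Load a COSMIC-v2-style TSV: context labels in the first column."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        missing = set(CONTEXT_LABELS) - set(df.index)
        if missing:
            raise SignatureError(f"signature file lacks {len(missing)} context rows")
        df = df.loc[list(CONTEXT_LABELS)]
        return cls(list(df.columns), df.to_numpy())

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.profiles, index=list(CONTEXT_LABELS), columns=self.names).to_csv(
            path, sep="\t", index_label="context"
        )


@dataclass
class ContributionVector:
    """Fractional signature contributions for one sample.

    ``fractions`` sum to 1 for a nonzero spectrum; an all-zero spectrum
    yields all-zero fractions with ``empty_spectrum`` set.
    """

    sample_id: str
    names: list[str]
    fractions: np.ndarray
    residual_norm: float
    empty_spectrum: bool = False


@dataclass
class ContributionDelta:
    """Per-patient change in fractional contributions (recurrence minus primary)."""

    patient_id: str
    names: list[str]
    deltas: np.ndarray


def fit_contributions(spectrum: Spectrum96, sigs: SignatureMatrix) -> ContributionVector:
    """Refit a spectrum onto reference signatures by non-negative least squares.

    Solves min ||counts - profiles @ w||_2 s.t. w >= 0 with the Lawson-Hanson
    active-set algorithm (deterministic), then normalizes w to fractions.
    """
    counts = spectrum.counts
    if counts.sum() == 0:
        return ContributionVector(spectrum.sample_id, list(sigs.names), np.zeros(sigs.k), 0.0, True)
    w, rnorm = nnls(sigs.profiles, counts)
    total = w.sum()
    fractions = w / total if total > 0 else np.zeros_like(w)
    return ContributionVector(spectrum.sample_id, list(sigs.names), fractions, float(rnorm))


def select_signatures(contributions: Sequence[ContributionVector]) -> list[str]:
    """Short-list signatures whose mean fraction across samples is in the top half.

    Signatures with mean contribution >= the median of the per-signature
    means are retained (ties at the median kept), i.e. the upper two
    quartiles by mean contribution.
    """
    if len(contributions) == 0:
        raise SignatureError("signature selection requires at least one sample")
    names = contributions[0].names
    for c in contributions[1:]:
        if c.names != names:
            raise SignatureError("contribution vectors carry different signature sets")
    means = np.mean([c.fractions for c in contributions], axis=0)
    cutoff = np.median(means)
    return [n for n, m in zip(names, means) if m >= cutoff]


def contribution_delta(pt: ContributionVector, ibtr: ContributionVector) -> ContributionDelta:
    """Fractional contribution change from primary to recurrence (sums to ~0)."""
    if pt.names != ibtr.names:
        raise SignatureError("mismatched signature labels between pair members")
    return ContributionDelta(pt.sample_id, list(pt.names), ibtr.fractions - pt.fractions)


def base_change_frequencies(variants: Iterable) -> pd.Series:
    """Fractions of the 6 pyrimidine-centered substitution classes in a sample."""
    counts = pd.Series(0.0, index=list(SUBSTITUTION_CLASSES))
    for v in variants:
        ref, alt = v.ref, v.alt
        if ref in ("G", "A"):
            ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        counts[f"{ref}>{alt}"] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def contributions_to_frame(contributions: Sequence[ContributionVector]) -> pd.DataFrame:
    """Samples x signatures table of fitted fractions."""
    return pd.DataFrame(
        [c.fractions for c in contributions],
        index=[c.sample_id for c in contributions],
        columns=contributions[0].names if contributions else [],
    )
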