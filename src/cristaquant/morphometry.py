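"""Statistics over per-section EM morphometry annotations.

Works on manually annotated transmission-EM cross sections of
mitochondrial tubules: crista-junction (CJ) frequency normalized to
outer-membrane (OM) length, CJ diameter summaries, cristae-morphology
class fractions, junction/septum accounting, the one-way ANOVA used
for the across-condition comparisons, and the averaged line-profile
analysis used on fluorescence images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats

from .cluster_metric import Image2D

__all__ = [
    "TWO_WAY_CLASSES",
    "EIGHT_WAY_CLASSES",
    "SectionMorphometry",
    "AnovaResult",
    "CJFrequency",
    "DiameterSummary",
    "JunctionSeptaResult",
    "LineProfileResult",
    "cj_frequency",
    "diameter_summary",
    "anova_one_way",
    "morphology_fractions",
    "junction_septa_accounting",
    "mean_line_profile",
]

#: Default coarse morphology split: ordered lamellar cristae vs everything else.
TWO_WAY_CLASSES = ("wild_type", "aberrant")

#: A detailed class set for crista-membrane phenotypes.  The membership is
#: user-declarable; this default names the phenotypes commonly scored on
#: EM sections of MICOS-perturbed mitochondria.
EIGHT_WAY_CLASSES = (
    "lamellar",
    "short_lamellar",
    "single_large_cm",
    "stacked_cm",
    "onion_like",
    "tubular",
    "vesicular",
    "no_cm",
)


@dataclass(frozen=True)
class SectionMorphometry:
    """Annotations of one EM cross section of a mitochondrion.

    ``n_cj`` counts crista junctions; ``n_septum_junctions`` counts
    junctions formed by septa (matrix-dividing inner-membrane sheets),
    kept separate because on 2D sections septa junctions can be
    mistaken for CJs.  Diameters may be measured for only a subset of
    the junctions, hence ``len(cj_diameters_nm) <= n_cj``.
    """

    section_id: str
    condition: str
    om_length_um: float
    n_cj: int
    cj_diameters_nm: tuple[float, ...] = ()
    morphology_class: str = "wild_type"
    has_septum: bool = False
    n_septum_junctions: int = 0

    def __post_init__(self) -> None:
        if not (self.om_length_um > 0):
            raise ValueError("om_length_um must be > 0")
        if self.n_cj < 0 or self.n_septum_junctions < 0:
            raise ValueError("junction counts must be >= 0")
        if len(self.cj_diameters_nm) > self.n_cj:
            raise ValueError("more diameters than crista junctions")
        if self.n_septum_junctions > 0 and not self.has_septum:
            raise ValueError("septum junctions require has_septum")
        object.__setattr__(
            self, "cj_diameters_nm", tuple(float(d) for d in self.cj_diameters_nm)
        )

    @property
    def n_junctions_total(self) -> int:
        return self.n_cj + self.n_septum_junctions


@dataclass(frozen=True)
class AnovaResult:
    """One-way fixed-effects ANOVA outcome.

    ``degenerate`` marks zero within-group variance: with nonzero
    between-group variance F is reported as +inf and p as the
    distribution limit 0; with all observations identical F and p are
    undefined (NaN).
    """

    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class CJFrequency:
    """CJ frequency for one condition, junctions per micrometre of OM."""

    pooled_rate: float
    per_section_rates: tuple[float, ...]
    sem: float
    n_sections: int


@dataclass(frozen=True)
class DiameterSummary:
    mean_nm: float
    sd_nm: float
    n: int
    is_defined: bool = True


@dataclass(frozen=True)
class JunctionSeptaResult:
    """Section-level junction and septum accounting for two conditions.

    ``prevalence`` is the fraction of sections with at least one
    junction of any kind; ``septum_frac`` the fraction of those
    junction-bearing sections whose junctions are septum-associated;
    ``cristae_cj_prevalence = prevalence * (1 - septum_frac)`` the
    prevalence of genuine (non-septum) CJs, and ``relative_decrease``
    the drop of that quantity from control to test.
    """

    prevalence_ctrl: float
    prevalence_test: float
    septum_frac_ctrl: float
    septum_frac_test: float
    cristae_cj_prevalence_ctrl: float
    cristae_cj_prevalence_test: float
    relative_decrease: float
    is_defined: bool = True


@dataclass(frozen=True)
class LineProfileResult:
    """Averaged normalized intensity profile along a set of lines."""

    positions_nm: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    profiles: np.ndarray
    degenerate: bool = False


# ---------------------------------------------------------------------------
# CJ frequency and diameters


def cj_frequency(sections: list[SectionMorphometry]) -> dict[str, CJFrequency]:
    """Per-condition CJ frequency normalized to OM length.

    The headline ``pooled_rate`` is the ratio of totals,
    sum(n_cj) / sum(om_length_um); per-section rates and their SEM are
    returned alongside for error bars.
    """
    if not sections:
        raise ValueError("no sections given")
    out: dict[str, CJFrequency] = {}
    for condition in dict.fromkeys(s.condition for s in sections):
        group = [s for s in sections if s.condition == condition]
        total_len = sum(s.om_length_um for s in group)
        rates = tuple(s.n_cj / s.om_length_um for s in group)
        sem = (
            float(np.std(rates, ddof=1) / math.sqrt(len(rates)))
            if len(rates) > 1
            else float("nan")
        )
        out[condition] = CJFrequency(
            pooled_rate=sum(s.n_cj for s in group) / total_len,
            per_section_rates=rates,
            sem=sem,
            n_sections=len(group),
        )
    return out


def diameter_summary(
    sections: list[SectionMorphometry], condition: str
) -> DiameterSummary:
    """Pooled mean and sample SD of CJ diameters for one condition."""
    diam = [d for s in sections if s.condition == condition for d in s.cj_diameters_nm]
    if not diam:
        return DiameterSummary(float("nan"), float("nan"), 0, is_defined=False)
    arr = np.asarray(diam, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return DiameterSummary(float(arr.mean()), sd, int(arr.size))


# ---------------------------------------------------------------------------
# One-way ANOVA


def anova_one_way(groups: list[list[float]]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA.

    F = (SSB / df_between) / (SSW / df_within) with the p-value from
    the F distribution.  Requires at least two groups with at least
    two finite observations each.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise ValueError(f"group {i} has fewer than two values")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"group {i} contains non-finite values")
    n_total = sum(a.size for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(float("nan"), df_b, df_w, float("nan"), degenerate=True)
        return AnovaResult(float("inf"), df_b, df_w, 0.0, degenerate=True)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p)


# ---------------------------------------------------------------------------
# Morphology classes


def morphology_fractions(
    sections: list[SectionMorphometry],
    class_set: tuple[str, ...] = TWO_WAY_CLASSES,
) -> dict[str, dict]:
    """Per-condition fractions of sections in each morphology class.

    Every section's class must belong to ``class_set``; an unknown
    label raises an error naming it.  Fractions sum to 1 per condition
    and the section count n is reported alongside.
    """
    if not sections:
        raise ValueError("no sections given")
    for s in sections:
        if s.morphology_class not in class_set:
            raise ValueError(
                f"unknown morphology class {s.morphology_class!r} "
                f"(declared classes: {class_set})"
            )
    out: dict[str, dict] = {}
    for condition in dict.fromkeys(s.condition for s in sections):
        group = [s for s in sections if s.condition == condition]
        n = len(group)
        fractions = {
            c: sum(1 for s in group if s.morphology_class == c) / n for c in class_set
        }
        out[condition] = {"fractions": fractions, "n": n}
    return out


# ---------------------------------------------------------------------------
# Junction / septum accounting


def _prevalence_and_septum_frac(
    sections: list[SectionMorphometry], mode: str
) -> tuple[float, float]:
    bearing = [s for s in sections if s.n_junctions_total >= 1]
    prevalence = len(bearing) / len(sections)
    if not bearing:
        return prevalence, 0.0
    if mode == "section":
        septum_frac = sum(1 for s in bearing if s.has_septum) / len(bearing)
    elif mode == "junction":
        total = sum(s.n_junctions_total for s in bearing)
        septum_frac = sum(s.n_septum_junctions for s in bearing) / total
    else:
        raise ValueError(f"unknown accounting mode {mode!r}")
    return prevalence, septum_frac


def junction_septa_accounting(
    sections_ctrl: list[SectionMorphometry],
    sections_test: list[SectionMorphometry],
    mode: str = "section",
) -> JunctionSeptaResult:
    """Junction prevalence and septum-associated share, control vs test.

    ``mode="section"`` (default) scores a junction-bearing section as
    septum-associated or not, matching quantification of sections
    exhibiting septa; ``mode="junction"`` counts individual junctions.
    ``relative_decrease`` is undefined (flagged) when the control
    cristae-CJ prevalence is zero.
    """
    if not sections_ctrl or not sections_test:
        raise ValueError("both section lists must be nonempty")
    prev_c, sep_c = _prevalence_and_septum_frac(sections_ctrl, mode)
    prev_t, sep_t = _prevalence_and_septum_frac(sections_test, mode)
    cj_prev_c = prev_c * (1.0 - sep_c)
    cj_prev_t = prev_t * (1.0 - sep_t)
    if cj_prev_c == 0.0:
        return JunctionSeptaResult(
            prev_c, prev_t, sep_c, sep_t, cj_prev_c, cj_prev_t,
            float("nan"), is_defined=False,
        )
    return JunctionSeptaResult(
        prev_c, prev_t, sep_c, sep_t, cj_prev_c, cj_prev_t,
        1.0 - cj_prev_t / cj_prev_c,
    )


# ---------------------------------------------------------------------------
# Line profiles


def mean_line_profile(
    image: Image2D,
    lines: list[tuple[tuple[float, float], tuple[float, float]]],
    n_samples: int = 100,
    normalization: str = "minmax",
) -> LineProfileResult:
    """Normalized, averaged intensity profiles along straight lines.

    Each line is a ((x0_nm, y0_nm), (x1_nm, y1_nm)) pair in physical
    image coordinates (origin top-left, x = column direction).  Each
    profile is sampled at ``n_samples`` equidistant points by bilinear
    interpolation, normalized — ``"minmax"`` (default) maps it onto
    [0, 1] via (p - min)/(max - min); ``"max"`` divides by the maximum
    only — then the profiles are averaged pointwise.  All lines must
    share one length so positions align.  A flat profile cannot be
    normalized; it is left as zeros and the result is flagged
    degenerate.
    """
    if not lines:
        raise ValueError("need at least one line")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if normalization not in ("minmax", "max"):
        raise ValueError(f"unknown normalization {normalization!r}")
    px = image.pixel_size_nm
    ny, nx = image.shape
    lengths = []
    profiles = []
    degenerate = False
    for (x0, y0), (x1, y1) in lines:
        length = math.hypot(x1 - x0, y1 - y0)
        if length == 0.0:
            raise ValueError("zero-length line")
        for x, y in ((x0, y0), (x1, y1)):
            if not (0.0 <= x <= (nx - 1) * px and 0.0 <= y <= (ny - 1) * px):
                raise ValueError(f"line endpoint ({x}, {y}) nm outside the image")
        lengths.append(length)
        t = np.linspace(0.0, 1.0, n_samples)
        cols = (x0 + t * (x1 - x0)) / px
        rows = (y0 + t * (y1 - y0)) / px
        prof = ndimage.map_coordinates(
            image.pixels, np.vstack([rows, cols]), order=1, mode="nearest"
        )
        lo, hi = float(prof.min()), float(prof.max())
        if hi == lo:
            degenerate = True
            prof = np.zeros_like(prof)
        elif normalization == "minmax":
            prof = (prof - lo) / (hi - lo)
        else:
            prof = prof / hi
        profiles.append(prof)
    if not np.allclose(lengths, lengths[0], rtol=1e-9):
        raise ValueError("all lines must have the same length for averaging")
    arr = np.vstack(profiles)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(n_samples)
    return LineProfileResult(
        positions_nm=np.linspace(0.0, lengths[0], n_samples),
        mean=arr.mean(axis=0),
        sd=sd,
        profiles=arr,
        degenerate=degenerate,
    )
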