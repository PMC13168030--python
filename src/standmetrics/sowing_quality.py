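"""Sowing-quality indices from within-row plant spacings (ISO 7256/1-1984).

The seeding-equipment test method normalizes each measured spacing d_i by
the planter's target spacing d_ref, S_i = d_i / d_ref, and classifies the
ratios into five intervals:

    bin 1: [0, 0.5]        short interval -> a multiple (extra seed)
    bin 2: (0.5, 1.5]      qualified (normal) interval
    bin 3: (1.5, 2.5]      one skipped placement
    bin 4: (2.5, 3.5]      two skipped placements
    bin 5: (3.5, inf)      three (or more) skipped placements

From the interval counts n'1..n'5 the seeding counts follow:

    n2 = n'1                                (multiples)
    n1 = (n'1 + n'2 + n'3 + n'4 + n'5) - 2*n2   (normal placements)
    n0 = n'3 + 2*n'4 + 3*n'5                (misses, weighted by skip count)
    N' = n'2 + 2*n'3 + 3*n'4 + 4*n'5        (total theoretical intervals)

which satisfy n1 + n2 + n0 = N' identically, so the three indices

    QFI = 100 * n1 / N'   (Quality of Feed Index)
    MUL = 100 * n2 / N'   (Multiple Index)
    MI  = 100 * n0 / N'   (Miss Index)

always sum to 100%.  Dispersion of the qualified ratios is summarized by
their mean S-bar, population standard deviation sigma, and CV = 100*sigma
(S-bar is ~1 by construction, so this matches the classical CV to second
order; ``cv_normalize_by_mean`` switches to 100*sigma/S-bar).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpacingSeries",
    "BinCounts",
    "SeedingCounts",
    "QualityReport",
    "normalize",
    "bin_ratios",
    "derive_counts",
    "indices",
    "qualified_stats",
    "evaluate",
]

#: Upper edges of the ratio intervals; each bin is closed above, open below
#: (bin 1 is closed at both ends: [0, 0.5]).
BIN_EDGES = (0.5, 1.5, 2.5, 3.5)


@dataclass
class SpacingSeries:
    """Ordered within-row spacings in meters plus the planter's target spacing."""

    spacings: np.ndarray
    target: float

    def __post_init__(self) -> None:
        self.spacings = np.asarray(self.spacings, dtype=float).ravel()
        if not self.target > 0:
            raise ValueError("target spacing must be positive")
        if self.spacings.size and (self.spacings < 0).any():
            raise ValueError("spacings must be non-negative")

    @property
    def ratios(self) -> np.ndarray:
        return self.spacings / self.target

    def __len__(self) -> int:
        return int(self.spacings.size)


@dataclass(frozen=True)
class BinCounts:
    """Counts n'1..n'5 of normalized ratios per ISO interval."""

    n1p: int
    n2p: int
    n3p: int
    n4p: int
    n5p: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.as_tuple()):
            raise ValueError("bin counts must be non-negative")

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.n1p, self.n2p, self.n3p, self.n4p, self.n5p)

    @property
    def total(self) -> int:
        return sum(self.as_tuple())


@dataclass(frozen=True)
class SeedingCounts:
    """Derived seeding counts: multiples n2, normals n1, misses n0, intervals N'."""

    n2: int
    n1: int
    n0: int
    Np: int


@dataclass
class QualityReport:
    """Full sowing-quality evaluation of one spacing series.

    Percentages are carried at full precision; round only for display.
    ``valid`` is False when the derived normal count n1 came out negative
    (a pathological stand dominated by multiples) — the indices are still
    reported, unclamped, with a warning.
    """

    qfi_pct: float
    mul_pct: float
    mi_pct: float
    s_bar: float
    sigma: float
    cv_pct: float
    bins: BinCounts
    counts: SeedingCounts
    valid: bool = True
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "qfi_pct": self.qfi_pct,
            "mul_pct": self.mul_pct,
            "mi_pct": self.mi_pct,
            "s_bar": self.s_bar,
            "sigma": self.sigma,
            "cv_pct": self.cv_pct,
            "bins": {
                "n1p": self.bins.n1p,
                "n2p": self.bins.n2p,
                "n3p": self.bins.n3p,
                "n4p": self.bins.n4p,
                "n5p": self.bins.n5p,
            },
            "counts": {
                "n0": self.counts.n0,
                "n1": self.counts.n1,
                "n2": self.counts.n2,
                "N": self.counts.Np,
            },
            "valid": self.valid,
            "warnings": list(self.warnings),
        }


def normalize(series: SpacingSeries) -> np.ndarray:
    """Normalized spacing ratios S_i = d_i / d_ref, order preserved."""
    return series.ratios


def bin_ratios(ratios) -> BinCounts:
    """Classify normalized ratios into the five ISO intervals.

    Boundary values belong to the lower bin: 0.5 is a multiple, 1.5 is
    qualified, 2.5 a single miss, 3.5 a double miss.
    """
    r = np.asarray(ratios, dtype=float).ravel()
    if r.size and (r < 0).any():
        raise ValueError("ratios must be non-negative")
    # side='left' puts exact edge values into the lower interval
    idx = np.searchsorted(BIN_EDGES, r, side="left")
    counts = np.bincount(idx, minlength=5)
    return BinCounts(*(int(c) for c in counts))


def derive_counts(b: BinCounts) -> SeedingCounts:
    """Seeding counts from interval counts.

    Each short interval (bin 1) merges what should have been two normal
    intervals around an extra plant, hence the -2*n2 correction to n1; a
    bin-k interval (k >= 3) spans k-1 theoretical intervals of which k-2
    are misses... weighted as n0 = n'3 + 2n'4 + 3n'5.  The construction
    guarantees n1 + n2 + n0 = N'.
    """
    n2 = b.n1p
    n1 = b.total - 2 * n2
    n0 = b.n3p + 2 * b.n4p + 3 * b.n5p
    Np = b.n2p + 2 * b.n3p + 3 * b.n4p + 4 * b.n5p
    return SeedingCounts(n2=n2, n1=n1, n0=n0, Np=Np)


def indices(c: SeedingCounts) -> tuple[float, float, float]:
    """(QFI, MUL, MI) percentages; requires at least one theoretical interval."""
    if c.Np <= 0:
        raise ValueError("no theoretical intervals (N' = 0): cannot evaluate")
    return (
        100.0 * c.n1 / c.Np,
        100.0 * c.n2 / c.Np,
        100.0 * c.n0 / c.Np,
    )


def qualified_stats(
    ratios,
    sigma_formula: str = "corrected",
    cv_normalize_by_mean: bool = False,
) -> tuple[float, float, float]:
    """Mean, standard deviation and CV% of the qualified ratios (bin 2).

    ``sigma_formula='corrected'`` (default) uses the population standard
    deviation about the mean.  ``'as_printed'`` uses the raw second-moment
    form sqrt(sum(S_i^2)/n'2) — an RMS, kept only for auditing: for ratios
    near 1 it returns ~1, i.e. a CV near 100%, which is not a dispersion
    measure.  Returns (nan, nan, nan) when no ratio is qualified.
    """
    r = np.asarray(ratios, dtype=float).ravel()
    q = r[(r > BIN_EDGES[0]) & (r <= BIN_EDGES[1])]
    if q.size == 0:
        return (float("nan"), float("nan"), float("nan"))
    s_bar = float(np.mean(q))
    if sigma_formula == "corrected":
        sigma = float(np.sqrt(np.mean((q - s_bar) ** 2)))
    elif sigma_formula == "as_printed":
        sigma = float(np.sqrt(np.mean(q**2)))
    else:
        raise ValueError(f"unknown sigma_formula {sigma_formula!r}")
    cv = 100.0 * (sigma / s_bar if cv_normalize_by_mean else sigma)
    return (s_bar, sigma, cv)


def evaluate(
    series: SpacingSeries,
    sigma_formula: str = "corrected",
    cv_normalize_by_mean: bool = False,
) -> QualityReport:
    """Full evaluation: normalize -> bin -> derive counts -> indices + dispersion."""
    if len(series) == 0:
        raise ValueError("empty spacing series: nothing to evaluate")
    ratios = normalize(series)
    bins = bin_ratios(ratios)
    counts = derive_counts(bins)
    qfi, mul, mi = indices(counts)
    s_bar, sigma, cv = qualified_stats(
        ratios, sigma_formula=sigma_formula, cv_normalize_by_mean=cv_normalize_by_mean
    )
    warnings: list[str] = []
    valid = True
    if counts.n1 < 0:
        valid = False
        warnings.append(
            f"derived normal count n1 = {counts.n1} < 0: stand dominated by "
            "short intervals; indices reported unclamped"
        )
    if bins.n2p == 0:
        warnings.append("no qualified intervals: S-bar/sigma/CV undefined")
    return QualityReport(
        qfi_pct=qfi,
        mul_pct=mul,
        mi_pct=mi,
        s_bar=s_bar,
        sigma=sigma,
        cv_pct=cv,
        bins=bins,
        counts=counts,
        valid=valid,
        warnings=warnings,
    )
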