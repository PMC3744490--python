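"""Sample-level charcoal assemblage statistics.

The scientific payoff of volumetric charcoal measurement is at the sample
level: expressing charcoal abundance as *total volume* rather than
particle count. Differential fragmentation during transport can multiply
counts without changing the amount of charcoal, so two samples can rank
oppositely by count and by volume. The estimator used here is

    total volume = (particle count in the slide) × (median particle
    volume of a measured subset),

reported in mm³. The module also provides descriptive size statistics,
manual-vs-rendered overestimate factors, the area→volume linear
calibration (thin oblate particles give an approximately proportional
area–volume relationship, V ≈ 13·A), tie-corrected Kruskal–Wallis group
comparison, and dispersion ("size sorting") metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .morphometrics import ParticleMorphometrics
from .stack_io import DataError

UM3_PER_MM3 = 1e9


@dataclass(frozen=True)
class AssemblageSummary:
    """Descriptive statistics of particle volume and area for one sample."""

    sample_id: str
    n: int
    mean_volume: float  # µm³
    median_volume: float
    se_volume: float
    min_volume: float
    max_volume: float
    mean_area: float  # µm²
    median_area: float
    se_area: float
    min_area: float
    max_area: float
    area_metric: str = "surface_area"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DataError("summary requires n >= 1")


@dataclass(frozen=True)
class TotalVolumeEstimate:
    """count × median-particle-volume, carried at full precision in mm³."""

    particle_count: int
    median_particle_volume: float  # mm³
    estimated_total: float  # mm³

    def display(self, decimals: int = 4) -> tuple[float, float]:
        """Rounded (median, total) for reporting; rounding happens only here."""
        return (
            round(self.median_particle_volume, decimals),
            round(self.estimated_total, decimals),
        )


@dataclass(frozen=True)
class RegressionFit:
    """Linear fit of particle volume (µm³) on area (µm²)."""

    slope: float  # µm³ per µm²
    intercept: float  # µm³
    r_squared: float
    through_origin: bool
    n: int


@dataclass(frozen=True)
class GroupComparison:
    """Tie-corrected Kruskal–Wallis H with a chi-square p-value."""

    H: float
    p_value: float
    df: int
    group_ns: tuple[int, ...]
    log10_p: float = field(default=float("nan"))


@dataclass(frozen=True)
class SortingMetrics:
    """Dispersion of particle volumes; lower = better sorted assemblage."""

    cv: float  # coefficient of variation, SD/mean
    qcd: float  # quartile coefficient of dispersion, (Q3-Q1)/(Q3+Q1)


@dataclass(frozen=True)
class RankedSeries:
    """Values sorted ascending with 1-based ranks and the median marked."""

    values: np.ndarray
    ranks: np.ndarray
    median: float
    median_rank: float  # (n + 1) / 2, fractional for even n


def _volumes_areas(
    records: list[ParticleMorphometrics], area_metric: str
) -> tuple[np.ndarray, np.ndarray]:
    if area_metric not in ("surface_area", "projected_area"):
        raise DataError(f"unknown area metric {area_metric!r}")
    vols = np.array([r.volume_um3 for r in records], dtype=float)
    attr = "surface_area_um2" if area_metric == "surface_area" else "projected_area_um2"
    areas = np.array([getattr(r, attr) for r in records], dtype=float)
    return vols, areas


def summarize(
    records: list[ParticleMorphometrics],
    sample_id: str,
    area_metric: str = "surface_area",
) -> AssemblageSummary:
    """Mean/median/SE/min/max of volume and area over one sample.

    Median for even n is the average of the two central order statistics;
    the standard error is the sample (n−1) SD over √n, 0 for n = 1.
    """
    if not records:
        raise DataError("cannot summarize an empty record list")
    vols, areas = _volumes_areas(records, area_metric)
    n = len(vols)

    def se(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0

    return AssemblageSummary(
        sample_id=sample_id,
        n=n,
        mean_volume=float(vols.mean()),
        median_volume=float(np.median(vols)),
        se_volume=se(vols),
        min_volume=float(vols.min()),
        max_volume=float(vols.max()),
        mean_area=float(areas.mean()),
        median_area=float(np.median(areas)),
        se_area=se(areas),
        min_area=float(areas.min()),
        max_area=float(areas.max()),
        area_metric=area_metric,
    )


def estimate_total_volume(
    particle_count: int, median_particle_volume_um3: float
) -> TotalVolumeEstimate:
    """Total charcoal volume in a slide: count × median particle volume.

    The product is formed at full precision in µm³ and converted to mm³;
    rounding to 4 decimals happens only at display. (Using a pre-rounded
    mm³ median instead would visibly corrupt the total: 216 × 0.0012 mm³
    = 0.2592 ≠ 0.2651 mm³.)
    """
    if particle_count < 0:
        raise DataError(f"particle count must be >= 0, got {particle_count}")
    if median_particle_volume_um3 <= 0:
        raise DataError("median particle volume must be > 0")
    total_um3 = particle_count * median_particle_volume_um3
    return TotalVolumeEstimate(
        particle_count=particle_count,
        median_particle_volume=median_particle_volume_um3 / UM3_PER_MM3,
        estimated_total=total_um3 / UM3_PER_MM3,
    )


def overestimate_factor(manual: float, rendered: float) -> float:
    """Ratio of the manual L·W·D estimate to the rendered (mesh) volume."""
    if manual <= 0 or rendered <= 0:
        raise DataError("volumes must be positive")
    return manual / rendered


def area_volume_regression(
    records_or_areas,
    volumes: np.ndarray | None = None,
    through_origin: bool = False,
    area_metric: str = "surface_area",
) -> RegressionFit:
    """Least-squares fit of volume (µm³) on area (µm²).

    Accepts either a list of :class:`ParticleMorphometrics` or two arrays
    (areas, volumes). With ``through_origin`` the slope is Σxy/Σx² and r²
    is computed about the origin-constrained model (1 − SSres/Σy²,
    uncentered — it measures the fraction of the raw second moment
    explained, the conventional definition for no-intercept fits).
    """
    if volumes is None:
        vols, areas = _volumes_areas(list(records_or_areas), area_metric)
    else:
        areas = np.asarray(records_or_areas, dtype=float)
        vols = np.asarray(volumes, dtype=float)
    n = len(areas)
    if n < 3:
        raise DataError(f"regression requires n >= 3, got n = {n}")
    if (areas <= 0).any() or (vols <= 0).any():
        raise DataError("areas and volumes must be positive")
    if through_origin:
        slope = float(areas @ vols / (areas @ areas))
        resid = vols - slope * areas
        ss_res = float(resid @ resid)
        ss_tot = float(vols @ vols)
        r2 = 1.0 - ss_res / ss_tot
        return RegressionFit(slope=slope, intercept=0.0, r_squared=r2,
                             through_origin=True, n=n)
    if np.ptp(areas) == 0:
        raise DataError("constant areas: free-intercept regression is degenerate")
    slope, intercept = np.polyfit(areas, vols, deg=1)
    pred = slope * areas + intercept
    ss_res = float(((vols - pred) ** 2).sum())
    ss_tot = float(((vols - vols.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RegressionFit(slope=float(slope), intercept=float(intercept),
                         r_squared=r2, through_origin=False, n=n)


def predict_volume_from_area(area_um2: float, k: float = 13.0) -> float:
    """Convert a measured 2D area to a volume estimate: V = k·A.

    The default k = 13 µm³/µm² is the general-purpose calibration for
    slide-mounted oblate charcoal; it lets an ordinary transmitted-light
    area workflow approximate confocal volume estimates.
    """
    if area_um2 <= 0:
        raise DataError(f"area must be positive, got {area_um2}")
    if k <= 0:
        raise DataError(f"conversion factor must be positive, got {k}")
    return k * area_um2


def compare_groups(*groups) -> GroupComparison:
    """Tie-corrected Kruskal–Wallis test across two or more samples.

    H = [12/(N(N+1)) Σ Rⱼ²/nⱼ − 3(N+1)] / [1 − Σ(t³−t)/(N³−N)] with Rⱼ the
    rank sum of group j (average ranks over ties) and t the sizes of tie
    groups; p from the chi-square approximation with (groups − 1) df.
    All values identical across all groups gives H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise DataError("need at least two groups")
    ns = tuple(len(g) for g in groups)
    if min(ns) < 1:
        raise DataError("each group needs at least one value")
    pooled = np.concatenate(groups)
    N = len(pooled)
    if N < 3:
        raise DataError("need at least 3 values in total")
    ranks = sstats.rankdata(pooled)
    H_num = 0.0
    start = 0
    for n_j in ns:
        R_j = ranks[start : start + n_j].sum()
        H_num += R_j**2 / n_j
        start += n_j
    H = 12.0 / (N * (N + 1)) * H_num - 3.0 * (N + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(((tie_counts**3 - tie_counts).sum()) / (N**3 - N))
    if correction == 0.0:  # every value identical
        H = 0.0
    else:
        H = H / correction
    H = max(H, 0.0)
    df = len(groups) - 1
    p = float(sstats.chi2.sf(H, df)) if H > 0 else 1.0
    log10_p = float(sstats.chi2.logsf(H, df) / math.log(10)) if H > 0 else 0.0
    return GroupComparison(H=float(H), p_value=p, df=df, group_ns=ns, log10_p=log10_p)


def size_sorting(records_or_values) -> SortingMetrics:
    """Dispersion of particle volumes: CV and quartile coefficient.

    "Size sorting" is the narrowness of the size distribution — well
    sorted assemblages (low dispersion) suggest longer or more selective
    transport. Both metrics are scale-free, so they compare samples with
    very different absolute particle sizes.
    """
    values = records_or_values
    if values and isinstance(values[0], ParticleMorphometrics):
        values = [r.volume_um3 for r in values]
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise DataError("size sorting requires at least 2 particles")
    cv = float(x.std(ddof=1) / x.mean()) if x.mean() != 0 else float("nan")
    q1, q3 = np.percentile(x, [25, 75])
    qcd = float((q3 - q1) / (q3 + q1)) if (q3 + q1) != 0 else 0.0
    return SortingMetrics(cv=cv, qcd=qcd)


def ranked_distribution(records_or_values, metric: str = "volume") -> RankedSeries:
    """Values sorted ascending with ranks, plus the median annotation.

    This is the rank-size view used to display the full spectrum of
    particle sizes in a sample with the median marked.
    """
    values = records_or_values
    if values and isinstance(values[0], ParticleMorphometrics):
        attr = {"volume": "volume_um3", "surface_area": "surface_area_um2",
                "projected_area": "projected_area_um2"}.get(metric)
        if attr is None:
            raise DataError(f"unknown metric {metric!r}")
        values = [getattr(r, attr) for r in values]
    x = np.sort(np.asarray(values, dtype=float), kind="stable")
    if len(x) < 1:
        raise DataError("ranked distribution requires n >= 1")
    return RankedSeries(
        values=x,
        ranks=np.arange(1, len(x) + 1),
        median=float(np.median(x)),
        median_rank=(len(x) + 1) / 2.0,
    )


def plot_ranked_distributions(named_series: dict, path=None):
    """Rank-size charts (one panel per sample) with the median as a red line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(named_series)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3), squeeze=False)
    for ax, (name, series) in zip(axes[0], named_series.items()):
        ax.bar(series.ranks, series.values, width=1.0, color="0.3")
        ax.axhline(series.median, color="red", lw=1.2, label="median")
        ax.set_title(name)
        ax.set_xlabel("rank")
        ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
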