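"""Binding-position statistics: genomic mapping, Gaussian peak fits,
bootstrap errors, 5-kb window enrichment, and the associated tests.

Positions measured in um from the barrier anchor are mapped to kb from
cosL through the tether geometry (13 um of tether spanning the 48.5-kb
substrate at ~80% extension, i.e. ~0.268 um/kb), assuming every molecule
is anchored at the barrier center.  Distributions are binned at 1 kb and
fit with one or two Gaussians plus a constant background; enrichment of
molecules in a 5-kb window covering the modification relative to the
same window on an unmodified substrate quantifies site-specific loading.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .presets import GENOME_KB, GeometryParams

__all__ = [
    "BindingSet",
    "PeakFit",
    "EnrichmentResult",
    "map_to_kb",
    "fit_peaks",
    "bootstrap_stat",
    "BootstrapResult",
    "make_window_layout",
    "window_enrichment",
    "windows_t_test",
    "chi_squared_table",
    "capture_fraction",
]

OFF_DNA_TOL_KB = 2.0


def map_to_kb(
    position_um, geometry: GeometryParams | None = None
) -> np.ndarray:
    """Convert um-from-anchor to kb-from-cosL via the tether extension.

    Uses ``kb = um / (tether_um / genome_kb)``; with the default
    geometry, 13 um maps to 48.5 kb.  Positions are clipped nowhere;
    callers flag off-DNA records beyond ``genome_kb + OFF_DNA_TOL_KB``.
    """
    geometry = geometry or GeometryParams()
    pos = np.asarray(position_um, dtype=float)
    if np.any(pos < 0):
        raise ValueError("positions must be non-negative")
    return pos / geometry.um_per_kb


@dataclass
class BindingSet:
    """Per-molecule binding positions (kb) for one substrate.

    Only flow-toggle-verified on-DNA records enter histograms and
    enrichment statistics.
    """

    substrate: str
    positions_kb: np.ndarray
    flowcell: np.ndarray | None = None
    on_dna: np.ndarray | None = None
    genome_kb: float = GENOME_KB

    def __post_init__(self) -> None:
        self.positions_kb = np.asarray(self.positions_kb, dtype=float)
        if self.on_dna is None:
            self.on_dna = self.positions_kb <= self.genome_kb + OFF_DNA_TOL_KB
        self.on_dna = np.asarray(self.on_dna, dtype=bool)
        if self.flowcell is None:
            self.flowcell = np.zeros(len(self.positions_kb), dtype=int)

    @classmethod
    def from_um(
        cls, substrate: str, positions_um, geometry: GeometryParams | None = None, **kw
    ) -> "BindingSet":
        return cls(substrate, map_to_kb(positions_um, geometry), **kw)

    @property
    def valid_positions(self) -> np.ndarray:
        return self.positions_kb[self.on_dna]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "substrate": self.substrate,
                "flowcell": self.flowcell,
                "position_kb": self.positions_kb,
                "on_dna": self.on_dna,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BindingSet":
        (substrate,) = df["substrate"].unique()
        return cls(
            substrate,
            df["position_kb"].to_numpy(),
            flowcell=df["flowcell"].to_numpy() if "flowcell" in df else None,
            on_dna=df["on_dna"].to_numpy() if "on_dna" in df else None,
        )


@dataclass(frozen=True)
class PeakFit:
    """Gaussian peak-fit result: centers +- sd in kb, component weights."""

    centers_kb: tuple[float, ...]
    sds_kb: tuple[float, ...]
    weights: tuple[float, ...]
    background: float = 0.0
    ok: bool = True
    method: str = "histogram"
    note: str | None = None


def _multi_gauss(x, params, n_components, background):
    y = np.full_like(x, params[-1] if background else 0.0, dtype=float)
    for k in range(n_components):
        a, c, s = params[3 * k : 3 * k + 3]
        y = y + a * np.exp(-((x - c) ** 2) / (2.0 * s**2))
    return y


def fit_peaks(
    positions_kb,
    n_components: int = 1,
    window_kb: tuple[float, float] | None = None,
    bin_kb: float = 1.0,
    background: bool = True,
    method: str = "histogram",
) -> PeakFit:
    """Fit 1 or 2 Gaussians (plus constant background) to a binding
    histogram.

    The default fits binned counts (1-kb bins) by least squares,
    mirroring histogram-based peak fitting; ``method='mle'`` fits the raw
    sample instead (moments for one component, EM for two, no background
    term).  Samples smaller than 20 fall back to moment estimates; a
    zero-variance sample returns its value with sd flagged 0.
    """
    if isinstance(positions_kb, BindingSet):
        positions_kb = positions_kb.valid_positions
    x = np.sort(np.asarray(positions_kb, dtype=float))
    if window_kb is not None:
        x = x[(x >= window_kb[0]) & (x <= window_kb[1])]
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if len(x) == 0:
        raise ValueError("no positions in window")
    if np.ptp(x) == 0:
        return PeakFit((float(x[0]),), (0.0,), (1.0,), ok=False, note="degenerate")
    if len(x) < 20 or method == "mle":
        return _fit_peaks_mle(x, n_components, note="moment_fallback" if len(x) < 20 else None)

    lo = math.floor(x[0] / bin_kb) * bin_kb
    hi = math.ceil(x[-1] / bin_kb) * bin_kb
    edges = np.arange(lo, hi + bin_kb / 2, bin_kb)
    counts, _ = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # initial guesses from the highest bins
    order = np.argsort(counts)[::-1]
    c0 = [centers[order[0]]]
    if n_components == 2:
        for idx in order[1:]:
            if abs(centers[idx] - c0[0]) > 3 * bin_kb:
                c0.append(centers[idx])
                break
        else:
            c0.append(centers[order[0]] + 3 * bin_kb)
    sd0 = max(np.std(x) / n_components, bin_kb)
    p0 = []
    for c in c0:
        p0 += [counts.max(), c, sd0]
    p0.append(float(np.median(counts)) if background else 0.0)

    def model(xv, *params):
        return _multi_gauss(xv, np.asarray(params), n_components, background)

    try:
        popt, _ = optimize.curve_fit(
            model, centers, counts, p0=p0 if background else p0[:-1], maxfev=5000
        )
    except RuntimeError:
        return _fit_peaks_mle(x, n_components, note="histogram_fit_failed")
    comps = sorted(
        (
            (float(popt[3 * k + 1]), abs(float(popt[3 * k + 2])), float(popt[3 * k]))
            for k in range(n_components)
        ),
    )
    areas = np.array([a * s for c, s, a in comps])
    weights = areas / areas.sum() if areas.sum() > 0 else np.full(n_components, np.nan)
    return PeakFit(
        centers_kb=tuple(c for c, s, a in comps),
        sds_kb=tuple(s for c, s, a in comps),
        weights=tuple(weights),
        background=float(popt[-1]) if background else 0.0,
        method="histogram",
    )


def _fit_peaks_mle(x: np.ndarray, n_components: int, note=None) -> PeakFit:
    if n_components == 1:
        return PeakFit(
            (float(np.mean(x)),), (float(np.std(x, ddof=1)),), (1.0,),
            method="mle", note=note,
        )
    # two-component EM with deterministic quantile initialization
    mu = np.quantile(x, [0.25, 0.75])
    sd = np.full(2, max(np.std(x) / 2, 1e-3))
    w = np.array([0.5, 0.5])
    for _ in range(300):
        resp = np.stack(
            [w[k] * stats.norm.pdf(x, mu[k], sd[k]) for k in range(2)]
        )
        resp /= np.maximum(resp.sum(axis=0, keepdims=True), 1e-300)
        nk = resp.sum(axis=1)
        mu_new = (resp * x).sum(axis=1) / nk
        sd_new = np.sqrt((resp * (x - mu_new[:, None]) ** 2).sum(axis=1) / nk)
        w_new = nk / len(x)
        if np.allclose(mu_new, mu, atol=1e-8) and np.allclose(sd_new, sd, atol=1e-8):
            mu, sd, w = mu_new, sd_new, w_new
            break
        mu, sd, w = mu_new, np.maximum(sd_new, 1e-3), w_new
    order = np.argsort(mu)
    return PeakFit(
        tuple(float(m) for m in mu[order]),
        tuple(float(s) for s in sd[order]),
        tuple(float(v) for v in w[order]),
        method="mle",
        note=note,
    )


@dataclass(frozen=True)
class BootstrapResult:
    point: float
    sd: float
    ci_low: float
    ci_high: float
    n_resamples: int


_NAMED_STATS = {
    "mean": np.mean,
    "median": np.median,
    "std": lambda v: np.std(v, ddof=1),
}


def bootstrap_stat(
    sample, statistic="mean", n_resamples: int = 1000, seed=0
) -> BootstrapResult:
    """Nonparametric bootstrap (resampling with replacement) of a reducer.

    Returns the point estimate on the full sample, the bootstrap SD, and
    the 2.5/97.5 percentile interval.  Fewer than 100 resamples is
    allowed but warned against.
    """
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("sample must be non-empty")
    if n_resamples < 100:
        warnings.warn("fewer than 100 bootstrap resamples", stacklevel=2)
    fn = _NAMED_STATS[statistic] if isinstance(statistic, str) else statistic
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_resamples, x.size))
    reps = np.array([fn(x[row]) for row in idx])
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return BootstrapResult(
        float(fn(x)), float(reps.std(ddof=1)), float(lo), float(hi), n_resamples
    )


def make_window_layout(
    site_kb: float,
    width_kb: float = 5.0,
    n_windows: int = 8,
    genome_kb: float = GENOME_KB,
) -> tuple[np.ndarray, int]:
    """Contiguous equal-width windows with one window centered on a site.

    Returns ``(edges, target_index)`` where ``edges`` has
    ``n_windows + 1`` boundaries.  The target window is re-centered on
    the modification site; the remaining windows tile outward as far as
    the substrate allows.
    """
    lo = site_kb - width_kb / 2
    if lo < 0 or lo + width_kb > genome_kb:
        raise ValueError("target window does not fit on the substrate")
    n_below = min(int(lo // width_kb), n_windows - 1)
    n_above = n_windows - 1 - n_below
    while lo + (n_above + 1) * width_kb > genome_kb:
        n_above -= 1
        n_below += 1
        if n_below * width_kb > lo:
            raise ValueError("window layout does not fit on the substrate")
    start = lo - n_below * width_kb
    edges = start + width_kb * np.arange(n_windows + 1)
    return edges, n_below


@dataclass(frozen=True)
class EnrichmentResult:
    """Windowed enrichment of a modified substrate over a reference."""

    edges_kb: np.ndarray
    target_window: int
    target_freq: np.ndarray      # per-window normalized freq, modified
    reference_freq: np.ndarray   # per-window normalized freq, reference
    fold: float
    t_stat: float = math.nan
    p_value: float = math.nan
    note: str | None = None


def _window_freq(positions: np.ndarray, edges: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(positions, bins=edges)
    n = len(positions)
    return counts / n if n else np.full(len(edges) - 1, np.nan)


def window_enrichment(
    target: BindingSet,
    reference: BindingSet,
    edges_kb: np.ndarray | None = None,
    target_window: int | None = None,
    site_kb: float | None = None,
) -> EnrichmentResult:
    """Fold enrichment of molecules in the target window.

    Window frequencies are normalized by each substrate's total on-DNA
    molecule count; the fold is the modified-substrate frequency in the
    target window divided by the reference-substrate frequency in the
    same window.  Provide either an explicit layout or ``site_kb`` for
    the default eight 5-kb windows centered on the site.
    """
    if edges_kb is None:
        if site_kb is None:
            raise ValueError("provide a window layout or a site coordinate")
        edges_kb, target_window = make_window_layout(site_kb)
    edges_kb = np.asarray(edges_kb, dtype=float)
    if target_window is None or not 0 <= target_window < len(edges_kb) - 1:
        raise ValueError("target window index outside the layout")
    tpos, rpos = target.valid_positions, reference.valid_positions
    if len(tpos) == 0 or len(rpos) == 0:
        raise ValueError("both binding sets must be non-empty")
    tf = _window_freq(tpos, edges_kb)
    rf = _window_freq(rpos, edges_kb)
    note = None
    if rf[target_window] == 0:
        fold = math.nan
        note = "undefined fold: zero reference count in target window"
    else:
        fold = float(tf[target_window] / rf[target_window])
    return EnrichmentResult(edges_kb, target_window, tf, rf, fold, note=note)


def windows_t_test(group_a, group_b, permutations: int = 10000, seed: int = 0):
    """Two-tailed Welch t-test on normalized window frequencies.

    If either group has zero variance the t statistic is undefined;
    identical constant groups return (0, 1) and other degenerate cases
    fall back to a label-permutation test on the mean difference.
    Returns ``(t, p)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return _permutation_test(a, b, permutations, seed)
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        return _permutation_test(a, b, permutations, seed)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _permutation_test(a, b, permutations, seed):
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    count = 0
    for _ in range(permutations):
        rng.shuffle(pooled)
        diff = abs(pooled[: len(a)].mean() - pooled[len(a):].mean())
        if diff >= observed - 1e-15:
            count += 1
    return math.nan, (count + 1) / (permutations + 1)


@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    dof: int
    p_value: float
    expected: np.ndarray
    warning: str | None = None


def chi_squared_table(table) -> ChiSquaredResult:
    """Pearson chi-squared test of independence on a counts table.

    No continuity correction; expected counts below 1 are flagged in the
    result rather than raising.
    """
    obs = np.asarray(table, dtype=float)
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("table must contain non-negative integer counts")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("table has an all-zero margin")
    res = stats.chi2_contingency(obs, correction=False)
    warning = None
    if np.any(res.expected_freq < 1):
        warning = "expected count below 1 in at least one cell"
    return ChiSquaredResult(
        float(res.statistic), int(res.dof), float(res.pvalue),
        res.expected_freq, warning,
    )


def capture_fraction(center_kb: float, sd_kb: float, window_kb: tuple[float, float]) -> float:
    """Fraction of a Gaussian binding peak captured by a window.

    Reported as a configurable diagnostic (e.g. how much of a site peak a
    5-kb window spans), not as a fixed claim.
    """
    lo, hi = window_kb
    return float(
        stats.norm.cdf((hi - center_kb) / sd_kb) - stats.norm.cdf((lo - center_kb) / sd_kb)
    )
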