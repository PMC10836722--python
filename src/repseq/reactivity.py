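"""Reporter-coculture reactivity scoring and dose-response fitting.

The screening readout is a dual flow-cytometry reporter: a T cell-intrinsic
GFP signal plus HA staining of cocultured presenting cells. Percent-positive
signal is computed by Overton histogram subtraction of a mutant-peptide test
well against its wild-type-peptide control well, and a TCR is called reactive
only if it clears conservative mutant-signal thresholds while showing no
cross-reactivity to the wild-type peptide. Antibody binding assays are
summarized by four-parameter logistic (4PL) dose-response fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import AnalysisError, BinningError, ParameterError

CHANNELS = {"GFP", "HA", "other"}


@dataclass
class FlowHistogram:
    """Binned single-channel fluorescence distribution for one coculture well."""

    channel: str
    bin_edges: np.ndarray
    counts: np.ndarray
    label: str = ""

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ParameterError(f"unknown channel {self.channel!r}")
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ParameterError("bin_edges must be strictly increasing")
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ParameterError("counts must have one entry per bin")
        if np.any(self.counts < 0):
            raise ParameterError("counts must be non-negative")

    @property
    def n_events(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_events(cls, values, bin_edges, channel: str = "GFP", label: str = "") -> "FlowHistogram":
        """Bin raw per-event channel values with the given edges."""
        counts, _ = np.histogram(np.asarray(values, dtype=float), bins=np.asarray(bin_edges, dtype=float))
        return cls(channel=channel, bin_edges=np.asarray(bin_edges, dtype=float), counts=counts, label=label)


def overton_percent_positive(test: FlowHistogram, control: FlowHistogram, smooth_window: int = 1) -> float:
    """Overton percent positive of ``test`` over ``control``.

    Per-bin frequencies are normalized to each histogram's own event total
    (depth-invariant), then the positive part of their difference is summed:
    ``100 * sum_b max(0, f_test[b] - f_ctrl[b])``. Histograms must share their
    binning exactly; no silent rebinning is attempted.

    Raw per-bin subtraction is the default. At finite event counts it carries
    a positive sampling bias of order ``sqrt(occupied_bins / n_events)`` under
    the null; ``smooth_window`` (odd, in bins) optionally applies a moving
    average to both frequency vectors before subtraction to suppress it.
    """
    if test.bin_edges.shape != control.bin_edges.shape or not np.array_equal(test.bin_edges, control.bin_edges):
        raise BinningError("test and control histograms have different bin edges")
    if test.n_events == 0 or control.n_events == 0:
        raise ParameterError("both histograms must contain events")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ParameterError("smooth_window must be a positive odd number of bins")
    f_test = test.counts / test.n_events
    f_ctrl = control.counts / control.n_events
    if smooth_window > 1:
        kernel = np.full(smooth_window, 1.0 / smooth_window)
        f_test = np.convolve(f_test, kernel, mode="same")
        f_ctrl = np.convolve(f_ctrl, kernel, mode="same")
    return float(100.0 * np.maximum(0.0, f_test - f_ctrl).sum())


@dataclass(frozen=True)
class ReactivityThresholds:
    """Conservative screening thresholds (percent).

    ``min_gfp``/``min_ha`` are minimum mutant-peptide signals; ``max_wt_gfp``
    caps the mutant-independent signal against the wild-type peptide. The
    defaults are estimates chosen so that the weakest accepted activity on
    record (3.1% GFP / 24.9% HA, wild-type-negative) passes; they are not
    published constants and should be configured per assay.
    """

    min_gfp: float = 3.0
    min_ha: float = 20.0
    max_wt_gfp: float = 2.0


@dataclass
class ReactivityCall:
    tcr_id: str
    gfp_pct: float
    ha_pct: float
    gfp_pct_wt: float
    reactive: bool
    failed_criteria: list[str] = field(default_factory=list)


def call_reactive(
    gfp_mut: float,
    ha_mut: float,
    gfp_wt: float,
    thresholds: ReactivityThresholds = ReactivityThresholds(),
    tcr_id: str = "",
) -> ReactivityCall:
    """Call a TCR mutant-reactive, naming every violated criterion.

    Reactive requires mutant GFP >= min_gfp AND mutant HA >= min_ha AND
    wild-type GFP <= max_wt_gfp (the specificity rule: wild-type
    cross-reactivity disqualifies regardless of mutant signal).
    """
    for name, value in (("gfp_mut", gfp_mut), ("ha_mut", ha_mut), ("gfp_wt", gfp_wt)):
        if not 0.0 <= value <= 100.0:
            raise ParameterError(f"{name} must be a percentage in [0, 100], got {value}")
    failed = []
    if gfp_mut < thresholds.min_gfp:
        failed.append("min_gfp")
    if ha_mut < thresholds.min_ha:
        failed.append("min_ha")
    if gfp_wt > thresholds.max_wt_gfp:
        failed.append("max_wt_gfp")
    return ReactivityCall(
        tcr_id=tcr_id,
        gfp_pct=gfp_mut,
        ha_pct=ha_mut,
        gfp_pct_wt=gfp_wt,
        reactive=not failed,
        failed_criteria=failed,
    )


# ---------------------------------------------------------------------------
# Four-parameter logistic dose-response
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseFit:
    """4PL fit: OD = bottom + (top - bottom) / (1 + (ec50 / c) ** hill)."""

    bottom: float
    top: float
    ec50: float | None
    hill: float
    rss: float
    converged: bool


def _four_pl(conc: np.ndarray, bottom: float, top: float, log10_ec50: float, hill: float) -> np.ndarray:
    # evaluated on log-concentration scale for numerical stability
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log10_ec50 - np.log10(conc))))


def fit_4pl(concentrations, od, *, descending: bool = False) -> DoseResponseFit:
    """Least-squares 4PL fit with multi-start initialization.

    Fitting runs on the log-concentration scale with four EC50 starts spanning
    the dose range to avoid local minima. A flat response cannot identify an
    EC50 and returns a failure flag instead of a number.
    """
    conc = np.asarray(concentrations, dtype=float)
    od = np.asarray(od, dtype=float)
    if conc.shape != od.shape or conc.ndim != 1:
        raise ParameterError("concentrations and od must be matching 1-D vectors")
    if len(conc) < 5:
        raise ParameterError("at least 5 dose points are required")
    if len(np.unique(conc)) < 2:
        raise ParameterError("at least 2 distinct concentrations are required")
    if np.any(conc <= 0):
        raise ParameterError("concentrations must be positive")

    span = float(np.ptp(od))
    if span < 1e-3 * max(1e-12, float(np.max(np.abs(od)))):
        return DoseResponseFit(
            bottom=float(np.mean(od)), top=float(np.mean(od)), ec50=None, hill=0.0, rss=0.0, converged=False
        )

    log_c = np.log10(conc)
    hill_sign = -1.0 if descending else 1.0

    def residuals(params):
        bottom, top, log_ec50, hill = params
        return _four_pl(conc, bottom, top, log_ec50, hill) - od

    best = None
    starts = np.linspace(log_c.min(), log_c.max(), 4)
    for log_ec50_0 in starts:
        for hill_0 in (hill_sign, 2.0 * hill_sign):
            x0 = np.array([od.min(), od.max(), log_ec50_0, hill_0])
            try:
                sol = least_squares(
                    residuals,
                    x0,
                    bounds=(
                        [-np.inf, -np.inf, log_c.min() - 3.0, -10.0],
                        [np.inf, np.inf, log_c.max() + 3.0, 10.0],
                    ),
                )
            except Exception:  # numerical failure of one start is not fatal
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)
    if best is None:
        return DoseResponseFit(bottom=np.nan, top=np.nan, ec50=None, hill=np.nan, rss=np.inf, converged=False)

    rss, (bottom, top, log_ec50, hill) = best
    if abs(top - bottom) < 0.02 * span:
        return DoseResponseFit(bottom=float(bottom), top=float(top), ec50=None, hill=float(hill), rss=rss, converged=False)
    return DoseResponseFit(
        bottom=float(min(bottom, top)),
        top=float(max(bottom, top)),
        ec50=float(10.0**log_ec50),
        hill=float(hill),
        rss=rss,
        converged=True,
    )


@dataclass
class CompetitionFit:
    ic50: float | None
    rss: float
    converged: bool
    bottom: float
    top: float
    hill: float


def fit_competition(competitor_conc, od) -> CompetitionFit:
    """Competitive-binding fit: a 4PL with descending response.

    The IC50 is the inflection concentration of the descending curve; flat
    (no-competition) data return a failure flag.
    """
    conc = np.asarray(competitor_conc, dtype=float)
    od = np.asarray(od, dtype=float)
    fit = fit_4pl(conc, od, descending=True)
    if fit.converged and np.ptp(od) > 0:
        lo_mean = np.mean(od[conc <= np.median(conc)])
        hi_mean = np.mean(od[conc > np.median(conc)])
        if hi_mean >= lo_mean:
            raise AnalysisError("competition data must show a descending response")
    return CompetitionFit(
        ic50=fit.ec50, rss=fit.rss, converged=fit.converged, bottom=fit.bottom, top=fit.top, hill=fit.hill
    )
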