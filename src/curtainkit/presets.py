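"""Named experiment presets: the measured conditions each synthetic
dataset emulates.

Each preset bundles the binding mixture, diffusion parameters, dwell-time
kinetics, tether geometry and camera optics for one experimental
condition (LacI on operator cassettes, quantum-dot-labeled PCNA on
flap/(CAG)13/homoduplex substrates, IPTG dissociation kinetics, and the
salt-series diffusion measurement).  Numeric defaults are the measured
values for those conditions: Gaussian binding-peak centers/widths, fitted
half-lives, the 13-um double-tether extension of the 48.5-kb substrate
(~80% of B-form contour), and the 50-ms camera frame interval.

Site-specific mixture weights for the PCNA presets are parameterized by
the measured fold enrichment of molecules in the 5-kb window covering the
cassette relative to a uniform (homoduplex) background; see
:func:`site_weight_for_fold`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from scipy.stats import norm

from .substrate import LAMBDA_LENGTH_BP

__all__ = [
    "GeometryParams",
    "OpticsParams",
    "SiteComponent",
    "ExperimentPreset",
    "PRESETS",
    "get_preset",
    "site_weight_for_fold",
    "GENOME_KB",
]

#: Substrate length in kb; binding coordinates live on [0, GENOME_KB].
GENOME_KB = LAMBDA_LENGTH_BP / 1000.0


@dataclass(frozen=True)
class GeometryParams:
    """Tether geometry of a double- or single-tethered curtain molecule."""

    tether_um: float = 13.0          # barrier-to-anchor separation
    genome_kb: float = GENOME_KB
    extension_factor: float = 0.8    # fraction of B-form contour length
    anchor_jitter_um: float = 1.25   # barrier width over which anchors scatter

    @property
    def um_per_kb(self) -> float:
        return self.tether_um / self.genome_kb


@dataclass(frozen=True)
class OpticsParams:
    """Camera/PSF model for rendered frame stacks (EMCCD at 60x)."""

    pixel_um: float = 0.2667
    psf_sigma_px: float = 1.2
    frame_interval_s: float = 0.05
    photons_per_frame: float = 2000.0
    background: float = 100.0        # mean background counts per pixel
    read_noise: float = 2.0          # Gaussian read noise, counts RMS
    loc_sigma_um: float = 0.030      # localization noise added to trajectories


@dataclass(frozen=True)
class SiteComponent:
    """One Gaussian component of a binding-position mixture (kb units).

    ``sd_kb`` is the observed histogram width, which already folds in the
    tether-anchor scatter at the barrier; components specified from design
    coordinates instead use ``jitter_kb`` to add uniform anchor broadening.
    """

    center_kb: float
    sd_kb: float
    weight: float
    jitter_kb: float = 0.0


@dataclass(frozen=True)
class ExperimentPreset:
    name: str
    kind: str  # binding | dwell | diffusion | salt_series | behavior
    sites: tuple[SiteComponent, ...] = ()
    background_weight: float = 0.0
    d_um2_s: float = 0.0                 # diffusion coefficient at c0
    salt_slope_um2_s_mM: float = 0.0
    salt_c0_mM: float = 50.0
    salt_series_mM: tuple[float, ...] = ()
    site_interaction: str = "none"       # none | reflecting | trapping
    interaction_site_kb: float | None = None
    dwell_half_life_s: float = 0.0
    observation_window_s: float = math.inf
    behavior_counts: dict[str, int] = field(default_factory=dict)
    n_reported: int = 0                  # sample size of the emulated dataset
    geometry: GeometryParams = field(default_factory=GeometryParams)
    optics: OpticsParams = field(default_factory=OpticsParams)

    def __post_init__(self) -> None:
        w = self.background_weight + sum(s.weight for s in self.sites)
        if self.kind == "binding" and not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ValueError(f"preset {self.name!r}: mixture weights sum to {w}")
        if any(s.weight < 0 for s in self.sites) or self.background_weight < 0:
            raise ValueError(f"preset {self.name!r}: negative mixture weight")
        if not 0 < self.geometry.extension_factor <= 1:
            raise ValueError(f"preset {self.name!r}: extension factor out of (0, 1]")

    def d_at(self, conc_mM: float) -> float:
        """Linear salt dependence D(c) = D0 + slope * (c - c0)."""
        return self.d_um2_s + self.salt_slope_um2_s_mM * (conc_mM - self.salt_c0_mM)


def site_weight_for_fold(
    fold: float,
    center_kb: float,
    sd_kb: float,
    window: tuple[float, float],
    genome_kb: float = GENOME_KB,
) -> float:
    """Mixture weight of a site component that yields a given window fold.

    With a fraction ``w`` of molecules site-bound (Gaussian at
    ``center_kb``) and ``1 - w`` uniform on the substrate, the expected
    normalized frequency in the window is ``w * p_site + (1 - w) * p_bg``
    where ``p_bg`` is the window's share of the substrate.  Solving
    ``freq = fold * p_bg`` for ``w`` encodes a measured enrichment as a
    mixture weight.
    """
    lo, hi = window
    p_bg = (hi - lo) / genome_kb
    p_site = norm.cdf((hi - center_kb) / sd_kb) - norm.cdf((lo - center_kb) / sd_kb)
    if p_site <= p_bg:
        raise ValueError("site component does not concentrate in the window")
    w = p_bg * (fold - 1.0) / (p_site - p_bg)
    if not 0 <= w <= 1:
        raise ValueError(f"fold {fold} not achievable (w = {w:.3f})")
    return w


def _binding(name, sites, n):
    bg = 1.0 - sum(s.weight for s in sites)
    return ExperimentPreset(
        name=name, kind="binding", sites=tuple(sites),
        background_weight=bg, n_reported=n,
    )


# Target window covering the site-A cassette (5 kb centered on 21.3 kb).
_SITE_A_WINDOW = (18.8, 23.8)
#: Measured fold enrichments in the site-A window relative to homoduplex.
FLAP_FOLD = 2.7
CAG_FOLD = 1.5

_W_FLAP = site_weight_for_fold(FLAP_FOLD, 21.2, 1.4, _SITE_A_WINDOW)
_W_CAG = site_weight_for_fold(CAG_FOLD, 21.3, 1.4, _SITE_A_WINDOW)

_LACI_PEAKS = {"A": (21.7, 1.0, 558), "B": (34.0, 1.5, 538), "C": (46.0, 2.3, 467)}

PRESETS: dict[str, ExperimentPreset] = {}


def _register(p: ExperimentPreset) -> ExperimentPreset:
    PRESETS[p.name] = p
    return p


for _s, (_c, _sd, _n) in _LACI_PEAKS.items():
    _register(_binding(f"LacI_site{_s}", [SiteComponent(_c, _sd, 0.92)], _n))

# Double-operator construct: nearly equal occupancy at sites B and C.
_register(_binding(
    "LacI_siteBC",
    [SiteComponent(34.0, 2.0, 0.46), SiteComponent(46.2, 2.2, 0.46)],
    525,
))

# Flap substrate with digoxigenin on the flap and on the free DNA end.
_register(_binding(
    "dig_flap_end",
    [SiteComponent(22.0, 0.8, 0.45), SiteComponent(47.5, 2.0, 0.45)],
    225,
))

_register(_binding("yPCNA_flap", [SiteComponent(21.2, 1.4, _W_FLAP)], 500))
_register(_binding("yPCNA_cag13", [SiteComponent(21.3, 1.4, _W_CAG)], 500))
_register(ExperimentPreset(
    name="yPCNA_homoduplex", kind="binding", background_weight=1.0, n_reported=500,
))

# IPTG-induced LacI dissociation kinetics (and the no-IPTG control).
_register(ExperimentPreset(
    name="LacI_IPTG_siteB", kind="dwell",
    dwell_half_life_s=21.0, observation_window_s=600.0, n_reported=63,
))
_register(ExperimentPreset(
    name="LacI_IPTG_siteC", kind="dwell",
    dwell_half_life_s=22.0, observation_window_s=600.0, n_reported=56,
))
_register(ExperimentPreset(
    name="LacI_noIPTG", kind="dwell",
    dwell_half_life_s=327.0, observation_window_s=600.0, n_reported=49,
))

# Free 1D diffusion of PCNA on double-tethered homoduplex DNA.
_register(ExperimentPreset(
    name="yPCNA_homoduplex_diffusion", kind="diffusion",
    d_um2_s=0.5, n_reported=30,
))

# Salt series: linear D(c) with the measured yPCNA slope.  At
# 0.25 um^2/s per mM the concentration span must stay narrow for D to
# remain in the regime where the first-10-interval MSD fit is unbiased
# on a 13-um tether (molecules rarely reach the tether ends within the
# 60-s record); the series probes D = 0.10, 0.15, 0.20 um^2/s.
_register(ExperimentPreset(
    name="yPCNA_salt_series", kind="salt_series",
    d_um2_s=0.10, salt_slope_um2_s_mM=0.25, salt_c0_mM=50.0,
    salt_series_mM=(50.0, 50.2, 50.4), n_reported=35,
))

# Encounter-behavior fixtures: exact category counts, matching the scored
# molecule tallies for each substrate.
_register(ExperimentPreset(
    name="yPCNA_flap_dynamics", kind="behavior",
    d_um2_s=0.5, interaction_site_kb=21.3,
    behavior_counts={"blocked": 36, "captured": 2, "bypass": 2},
    n_reported=40,
))
_register(ExperimentPreset(
    name="yPCNA_cag13_dynamics", kind="behavior",
    d_um2_s=0.5, interaction_site_kb=21.3,
    behavior_counts={"captured": 11, "blocked": 23, "bypass": 2},
    n_reported=36,
))
_register(ExperimentPreset(
    name="yPCNA_homoduplex_dynamics", kind="behavior",
    d_um2_s=0.5, interaction_site_kb=21.3,
    behavior_counts={"bypass": 40},
    n_reported=40,
))


def get_preset(name: str, **overrides) -> ExperimentPreset:
    """Look up a preset by name, optionally overriding fields."""
    try:
        preset = PRESETS[name]
    except KeyError:
        known = ", ".join(sorted(PRESETS))
        raise KeyError(f"unknown preset {name!r}; known presets: {known}") from None
    if overrides:
        preset = replace(preset, **overrides)
    return preset
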