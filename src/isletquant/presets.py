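"""Stage/condition presets for the synthetic islet generator.

A :class:`StagePreset` bundles every generator parameter for one
experimental condition: β-cell counts, per-compartment glucose-responsive
targets, Max ΔF/F0 amplitude distributions, vessel ingrowth depth, calcium
transient kinetics, mosaic co-expression, and (for the cultured mouse-islet
conditions) insulin-secretion and ensemble-calcium parameters.

Presets ship in ``presets.cfg``, a human-readable key=value registry.  Each
entry records, in its ``source``/``assumed`` fields, which numbers are
reported summary statistics and which are package assumptions.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, fields
from importlib import resources
from typing import Optional

__all__ = ["StagePreset", "load_registry", "get_preset", "preset_names"]

_FLOAT_FIELDS = (
    "n_cells_mean", "n_cells_sd",
    "frac_responsive_mantle", "frac_responsive_core",
    "target_responsive_mantle", "target_responsive_core",
    "amp_mean_mantle", "amp_sd_mantle", "amp_mean_core", "amp_sd_core",
    "vessel_penetration", "sync_group_prob",
    "onset_delay_mean", "onset_delay_sd", "tau_rise", "tau_decay",
    "coexpression_frac",
    "secretion_low_mean", "secretion_low_sd",
    "secretion_high_mean", "secretion_high_sd",
    "gsi_mean", "gsi_sd",
    "ca_low_pct_mean", "ca_low_pct_sd", "ca_high_pct_mean", "ca_high_pct_sd",
    "cell_radius", "beta_fill_frac",
)


@dataclass
class StagePreset:
    """All generator parameters for one experimental condition.

    Responsive cells may be specified either as per-compartment Bernoulli
    fractions (``frac_responsive_*`` in [0, 1]) or as expected per-islet
    counts (``target_responsive_*``); counts are converted to fractions per
    generated islet.  Amplitudes are dimensionless Max ΔF/F0 fractions
    (1.456 ≡ 145.6%); secretion is in ng/ml; ensemble calcium is percent of
    baseline (100 = no change).
    """

    name: str
    # geometry
    n_cells_mean: Optional[float] = None
    n_cells_sd: Optional[float] = None
    cell_radius: float = 3.5          # μm; β-cell diameter ≈ 7 μm
    beta_fill_frac: float = 0.12      # β-cell volume fraction of the islet
    # glucose responsiveness
    frac_responsive_mantle: Optional[float] = None
    frac_responsive_core: Optional[float] = None
    target_responsive_mantle: Optional[float] = None
    target_responsive_core: Optional[float] = None
    # Max ΔF/F0 amplitude distributions (dimensionless)
    amp_mean_mantle: Optional[float] = None
    amp_sd_mantle: Optional[float] = None
    amp_mean_core: Optional[float] = None
    amp_sd_core: Optional[float] = None
    # vasculature
    vessel_penetration: Optional[float] = None
    # transient kinetics (s)
    sync_group_prob: float = 0.3
    onset_delay_mean: float = 30.0
    onset_delay_sd: float = 10.0
    tau_rise: float = 8.0
    tau_decay: float = 30.0
    # mosaic second marker
    coexpression_frac: Optional[float] = None
    # secretion (ng/ml); low may instead be implied via GSI
    secretion_low_mean: Optional[float] = None
    secretion_low_sd: Optional[float] = None
    secretion_high_mean: Optional[float] = None
    secretion_high_sd: Optional[float] = None
    gsi_mean: Optional[float] = None
    gsi_sd: Optional[float] = None
    # ensemble calcium, percent-of-baseline scale
    ca_low_pct_mean: Optional[float] = None
    ca_low_pct_sd: Optional[float] = None
    ca_high_pct_mean: Optional[float] = None
    ca_high_pct_sd: Optional[float] = None
    # provenance notes from the registry
    source: str = ""
    assumed: str = ""

    def __post_init__(self) -> None:
        for name in ("frac_responsive_mantle", "frac_responsive_core",
                     "vessel_penetration", "sync_group_prob",
                     "coexpression_frac", "beta_fill_frac"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in (f.name for f in fields(self)
                     if f.name.endswith("_sd") or "_sd_" in f.name):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name}={v} must be >= 0")
        for name in ("amp_mean_mantle", "amp_mean_core"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name}={v} must be >= 0")
        if not (self.tau_rise < self.tau_decay):
            raise ValueError("tau_rise must be < tau_decay")
        if self.cell_radius <= 0:
            raise ValueError("cell_radius must be positive")

    @property
    def has_secretion(self) -> bool:
        return self.secretion_high_mean is not None and (
            self.secretion_low_mean is not None or self.gsi_mean is not None)

    @property
    def has_geometry(self) -> bool:
        return self.n_cells_mean is not None


def load_registry() -> dict[str, StagePreset]:
    """Parse the shipped ``presets.cfg`` into a name → preset mapping."""
    parser = configparser.ConfigParser(inline_comment_prefixes=("#",),
                                       interpolation=None)
    text = resources.files("isletquant").joinpath("presets.cfg").read_text()
    parser.read_string(text)
    registry: dict[str, StagePreset] = {}
    for section in parser.sections():
        kwargs: dict[str, object] = {"name": section}
        for key, raw in parser.items(section):
            if key in _FLOAT_FIELDS:
                kwargs[key] = float(raw)
            elif key in ("source", "assumed"):
                kwargs[key] = raw
            else:
                raise KeyError(f"unknown preset key {key!r} in [{section}]")
        registry[section] = StagePreset(**kwargs)
    return registry


def preset_names() -> list[str]:
    return sorted(load_registry())


def get_preset(name: str) -> StagePreset:
    registry = load_registry()
    try:
        return registry[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(registry))}"
        ) from None
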