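"""Run configuration: every analysis threshold, named once.

All spatial quantities are in the geometry's units (micrometres for retinal
recordings, degrees of visual angle for thalamic recordings); times are in
seconds, rates in spikes/s.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # -- geometry --------------------------------------------------------
    central_radius: float = 350.0        # fixed Central area radius
    distance_min_required: float = 450.0  # inclusion gate on edge distance
    units: str = "um"                     # "um" (retina) or "deg" (LGN)

    # -- asymmetry screen ------------------------------------------------
    theta_mai: float = 0.3       # motion asymmetry index threshold
    theta_nvs: float = 0.15      # normalized vector sum threshold
    theta_count: float = 2.0     # min mean spikes/repetition in the PD
    alpha: float = 0.05          # significance level for permutation test
    n_perm: int = 1000           # label permutations per cell
    exclude_post_leading_edge: bool = True  # drop leading-edge epoch from POST
    pre_from_annulus_entry: bool = True     # PRE starts at Distance_min entry

    # -- receptive-field estimation -------------------------------------
    sta_min_spikes: int = 300    # below this the RF is flagged unreliable
    sta_n_lags: int = 12
    polarity_ratio: float = 2.0  # ON if ON-count > ratio * OFF-count
    ds_threshold: float = 0.3    # grating DS index threshold
    exclude_classical_ds: bool = False  # DSGCs reported, not excluded

    # -- baseline --------------------------------------------------------
    baseline_window: float = 1.0  # final seconds of each inter-trial blank

    # -- seeds -----------------------------------------------------------
    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.central_radius >= self.distance_min_required:
            raise ValueError(
                "central_radius must be smaller than distance_min_required "
                f"({self.central_radius} >= {self.distance_min_required})"
            )
        if self.units not in ("um", "deg"):
            raise ValueError(f"unknown units {self.units!r}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def lgn_config(**overrides) -> RunConfig:
    """Config preset for thalamic recordings: degrees of visual angle,
    11.7 deg Central radius, screen-border exclusion at 15 deg."""
    base = dict(units="deg", central_radius=11.7, distance_min_required=15.0)
    base.update(overrides)
    return RunConfig(**base).validate()
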