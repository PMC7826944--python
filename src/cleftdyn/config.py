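"""Analysis configuration: one YAML-loadable object holding every knob.

Defaults consolidate the published protocol: D159/H363 cleft pair,
0.55/1.0 nm state thresholds, 0.35 nm / 30° hydrogen-bond criteria with a
10 ps stride and 30% report threshold, 0.13 nm GROMOS cutoff at 100 ps
stride, and 1.0 nm / 1 ns release calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .cleftkin import StateThresholds
from .hbond import HBondCriteria


@dataclass
class AnalysisConfig:
    topology: str | None = None
    trajectory: str | None = None
    output_dir: str = "cleftdyn_out"
    seed: int = 0

    # selections
    cleft_res_a: str = "resid 159"
    cleft_res_b: str = "resid 363"
    cofactor_sel: str = "resname NAP NDP"
    zn_sel: str = "resname ZN"
    protein_sel: str = "protein"
    fit_sel: str = "backbone"
    domains: tuple = (("rossmann", 1, 181), ("helical", 182, 387))
    monomer_chain: str = "D"

    # thresholds & strides
    closed_max_nm: float = 0.55
    open_min_nm: float = 1.0
    hbond_d_max_nm: float = 0.35
    hbond_angle_max_deg: float = 30.0
    hbond_stride_ps: float = 10.0
    hbond_min_fraction: float = 0.30
    cluster_cutoff_nm: float = 0.13
    cluster_stride_ps: float = 100.0
    release_threshold_nm: float = 1.0
    release_dwell_ps: float = 1000.0
    zn_shell_cutoff_nm: float = 0.35
    traj_dt_ps: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "closed_max_nm", "open_min_nm", "hbond_d_max_nm",
            "hbond_angle_max_deg", "hbond_stride_ps", "cluster_cutoff_nm",
            "cluster_stride_ps", "release_threshold_nm", "zn_shell_cutoff_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def thresholds(self) -> StateThresholds:
        return StateThresholds(self.closed_max_nm, self.open_min_nm)

    @property
    def hbond_criteria(self) -> HBondCriteria:
        return HBondCriteria(self.hbond_d_max_nm, self.hbond_angle_max_deg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "domains" in data:
            data["domains"] = tuple(tuple(d) for d in data["domains"])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
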