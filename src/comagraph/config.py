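"""Pipeline configuration: one structured object, YAML round-trip.

Every run writes the fully resolved configuration next to its outputs so
any result directory is self-describing and re-runnable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .graphs import DensityGrid
from .synthetic import CohortConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    input_dir: str = "cohort"
    output_dir: str = "results"
    # connectivity
    discard_first_k: int = 5
    fc_include_zeros: bool = False  # alternative positive-edge-mean convention
    # graph metrics
    densities: tuple = DensityGrid().densities
    gamma: float = 1.0
    n_restarts: int = 100
    seed: int = 0
    binarize: bool = False
    # statistics
    alpha: float = 0.05
    # prediction operating points
    spec_good: float = 0.90
    spec_poor: float = 1.00
    # synthetic cohort (for `simulate`)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def density_grid(self) -> DensityGrid:
        return DensityGrid(tuple(self.densities))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["densities"] = list(self.densities)
        d["cohort"]["eeg_probs_good"] = list(self.cohort.eeg_probs_good)
        d["cohort"]["eeg_probs_poor"] = list(self.cohort.eeg_probs_poor)
        d["cohort"]["hospitals"] = list(self.cohort.hospitals)
        d["cohort"]["arrest_to_mri_good"] = list(self.cohort.arrest_to_mri_good)
        d["cohort"]["arrest_to_mri_poor"] = list(self.cohort.arrest_to_mri_poor)
        return d


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_raw = raw.pop("cohort", {})
    for key in ("eeg_probs_good", "eeg_probs_poor", "hospitals",
                "arrest_to_mri_good", "arrest_to_mri_poor"):
        if key in cohort_raw:
            cohort_raw[key] = tuple(cohort_raw[key])
    if "densities" in raw:
        raw["densities"] = tuple(raw["densities"])
    cfg = PipelineConfig(**raw, cohort=CohortConfig(**cohort_raw))
    cfg.cohort.validate()
    cfg.density_grid()  # validates
    return cfg


def save_config(config: PipelineConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
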