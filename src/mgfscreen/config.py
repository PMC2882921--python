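"""Analysis configuration.

All thresholds of the screening pipeline live here so that every stage
(scaling, probe filtering, contrasts, classification) reads from a single
validated object.  Defaults reproduce the study conditions: arrays scaled to
a mean intensity of 100 with a signal floor of 1, probe sets discarded when
absent in >= 95% of samples, contrasts called significant at BH-adjusted
p <= 0.05 with fold change >= 2, a gene called "not expressed" below 5%
presence, and "aberrant" in tumor cells above 10% presence with zero
presence in normal plasma cells.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

#: Valid scales for the two-sample test.
TEST_SCALES = ("log2", "linear")


@dataclass
class AnalysisConfig:
    """Thresholds and numerical options for the whole pipeline.

    Parameters
    ----------
    scale_target : float
        Per-sample mean signal after scaling (arbitrary scanner units).
    signal_floor : float
        Values below this are raised to it after scaling.
    trim_fraction : float
        Fraction trimmed from each tail when computing the per-sample mean
        used for scaling (0 gives the plain arithmetic mean).
    noninformative_absent_frac : float
        A probe set is non-informative when its not-present fraction across
        all samples is >= this value.
    alpha : float
        Significance level applied to BH-adjusted p-values.
    min_fold_change : float
        Minimal ratio of group means for a contrast to count as overexpression.
    rescue_min_present_frac : float
        A gene enters the tumor compartment by the rescue rule when its
        presence fraction in tumor cells exceeds this value (default 0,
        i.e. at least one present call) while every environment population
        has zero present calls.
    not_expressed_max_present_frac : float
        Presence below this fraction counts as "not expressed".
    aberrant_min_mmc_present_frac : float
        Aberrant expression requires tumor presence strictly above this
        while normal bone-marrow plasma cells have zero present calls.
    test_scale : {"log2", "linear"}
        Scale on which the two-sample t-test runs; fold changes are always
        ratios of linear-scale means.
    equal_variance : bool
        Pooled-variance (Student) t-test when True, Welch when False.
    require_niche_cross_contrast : bool
        When True, a niche call additionally requires the stromal/osteoclast
        population to beat the other niche population.
    random_seed : int
        Seed for any randomised step driven by this configuration.
    """

    scale_target: float = 100.0
    signal_floor: float = 1.0
    trim_fraction: float = 0.0
    noninformative_absent_frac: float = 0.95
    alpha: float = 0.05
    min_fold_change: float = 2.0
    rescue_min_present_frac: float = 0.0
    not_expressed_max_present_frac: float = 0.05
    aberrant_min_mmc_present_frac: float = 0.10
    test_scale: str = "log2"
    equal_variance: bool = True
    require_niche_cross_contrast: bool = False
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_target <= 0:
            raise ValueError("scale_target must be positive")
        if self.signal_floor <= 0:
            raise ValueError("signal_floor must be positive")
        if not 0.0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        for name in (
            "noninformative_absent_frac",
            "rescue_min_present_frac",
            "not_expressed_max_present_frac",
            "aberrant_min_mmc_present_frac",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {value!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_fold_change < 1.0:
            raise ValueError("min_fold_change must be >= 1")
        if self.test_scale not in TEST_SCALES:
            raise ValueError(f"test_scale must be one of {TEST_SCALES}")
        self.random_seed = int(self.random_seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a configuration from a YAML mapping; missing keys keep defaults."""
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            return cls()
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
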