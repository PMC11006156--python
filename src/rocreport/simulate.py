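"""Two-class Gaussian (binormal) biomarker cohort simulator.

The default configuration emulates a screening-biomarker cohort of 300
subjects with equal class sizes: cases drawn from Normal(55, 10) and
controls from Normal(40, 10), on the scale of the hepatic steatosis index
(HSI) used to screen for non-alcoholic fatty liver disease (NAFLD).
Sampling is fully reproducible from the explicit seed (PCG64 generator);
no global RNG state is touched.  Simulated values are unbounded — marker
realism is not enforced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import BiomarkerDataset, from_arrays


@dataclass
class SimulationConfig:
    """Parameters of the binormal generator (marker units throughout)."""

    n_total: int = 300
    prevalence: float = 0.5
    mu_pos: float = 55.0
    sd_pos: float = 10.0
    mu_neg: float = 40.0
    sd_neg: float = 10.0
    seed: int = 0
    marker_name: str = "HSI"
    outcome_name: str = "NAFLD"

    def __post_init__(self) -> None:
        if self.n_total < 4:
            raise ValueError("n_total must be >= 4")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.sd_pos <= 0 or self.sd_neg <= 0:
            raise ValueError("class standard deviations must be positive")
        if self.n_positive < 2 or self.n_negative < 2:
            raise ValueError(
                "prevalence and n_total must give at least 2 subjects per class"
            )

    @property
    def n_positive(self) -> int:
        return int(round(self.prevalence * self.n_total))

    @property
    def n_negative(self) -> int:
        return int(self.n_total - self.n_positive)


def simulate_cohort(config: SimulationConfig) -> BiomarkerDataset:
    """Draw one cohort: cases first (label "1"), then controls (label "0")."""
    rng = np.random.default_rng(config.seed)
    pos = rng.normal(config.mu_pos, config.sd_pos, size=config.n_positive)
    neg = rng.normal(config.mu_neg, config.sd_neg, size=config.n_negative)
    marker = np.concatenate([pos, neg])
    outcome = np.concatenate(
        [np.ones(config.n_positive, dtype=int), np.zeros(config.n_negative, dtype=int)]
    )
    return from_arrays(
        marker,
        outcome,
        marker_name=config.marker_name,
        outcome_name=config.outcome_name,
        positive_label="1",
        negative_label="0",
    )


def theoretical_auc(config: SimulationConfig) -> float:
    """Closed-form binormal AUC: Phi((mu+ - mu-) / sqrt(sd+^2 + sd-^2)).

    Stated for the greater-is-positive orientation; the defaults give
    Phi(15 / (10 * sqrt(2))) ~= 0.8556.
    """
    delta = (config.mu_pos - config.mu_neg) / float(
        np.hypot(config.sd_pos, config.sd_neg)
    )
    return float(stats.norm.cdf(delta))


def write_cohort_csv(config: SimulationConfig, path) -> BiomarkerDataset:
    """Simulate and write the standard CSV consumed by ``data_io``."""
    data = simulate_cohort(config)
    data.to_csv(path)
    return data
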