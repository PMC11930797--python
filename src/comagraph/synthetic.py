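"""Synthetic two-group cohort generator.

Emulates a resting-state fMRI cohort of comatose post-cardiac-arrest
patients: each subject is a node-by-volume time series drawn from a
zero-mean multivariate normal with modular block covariance, where the
good- and poor-outcome groups differ only in a global coupling multiplier
applied to all off-diagonal covariance.  Categorical EEG patterns,
guideline predictors (pupils/SSEP, EEG class) and clinical covariates are
drawn from outcome-conditional distributions so every downstream contrast
is exercisable without patient data.

The generator is a pure function of its configuration: the same
:class:`CohortConfig` (including ``seed``) always yields the identical
cohort, subject by subject and bit by bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "build_block_covariance",
    "sample_subject",
    "generate_cohort",
    "cohort_metadata_frame",
]

#: EEG categories: 1 suppressed; 2 suppressed background with pathological
#: bursts / GPDs; 3 continuous activity; 4 epileptiform; 5 discontinuous or
#: heterogeneous burst suppression.
EEG_CATEGORIES = (1, 2, 3, 4, 5)

# Outcome-conditional EEG category probabilities.  Chosen so that continuous
# activity (category 3) dominates in good outcome and malignant patterns
# (1, 2, 4) are enriched in poor outcome; the implied marginal counts in a
# 44/26 cohort approximate the observed distribution 9/30/7/14 over
# categories 2, 3, 4, 5.
DEFAULT_EEG_PROBS_GOOD = (0.02, 0.05, 0.70, 0.05, 0.18)
DEFAULT_EEG_PROBS_POOR = (0.10, 0.25, 0.15, 0.20, 0.30)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the reference cohort: 44 good / 26 poor outcome
    subjects, 264 nodes, 220 volumes, and Table-1-style covariate
    distributions (arrest-to-MRI hours, three hospitals, comatose flag).
    """

    n_good: int = 44
    n_poor: int = 26
    n_nodes: int = 264
    n_volumes: int = 220
    n_modules: int = 8
    rho_within: float = 0.6
    rho_between: float = 0.2
    coupling_good: float = 0.9
    coupling_poor: float = 0.5
    noise_sd: float = 0.5
    seed: int = 0
    eeg_probs_good: tuple = DEFAULT_EEG_PROBS_GOOD
    eeg_probs_poor: tuple = DEFAULT_EEG_PROBS_POOR
    # pupils fixed and/or SSEP absent: essentially never in good outcome
    p_pupils_ssep_good: float = 0.02
    p_pupils_ssep_poor: float = 0.45
    # arrest-to-MRI interval, hours: Normal(mean, sd) per group
    arrest_to_mri_good: tuple = (59.0, 21.0)
    arrest_to_mri_poor: tuple = (66.0, 27.0)
    p_comatose_good: float = 0.36
    p_comatose_poor: float = 0.96
    hospitals: tuple = ("A", "B", "C")

    def validate(self) -> None:
        if self.n_good <= 0 or self.n_poor <= 0:
            raise ValueError("group sizes must be positive")
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if self.n_volumes < 3:
            raise ValueError("need at least 3 volumes")
        if not (1 <= self.n_modules <= self.n_nodes):
            raise ValueError("n_modules must be in [1, n_nodes]")
        if not (0.0 <= self.rho_within < 1.0):
            raise ValueError("rho_within must be in [0, 1)")
        if not (0.0 <= self.rho_between <= self.rho_within):
            raise ValueError("rho_between must be in [0, rho_within]")
        for name in ("coupling_good", "coupling_poor"):
            c = getattr(self, name)
            if not (0.0 < c <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("eeg_probs_good", "eeg_probs_poor"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (5,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"{name} must be 5 non-negative probabilities summing to 1")


@dataclass
class SubjectRecord:
    """One subject: time series plus outcome, EEG and clinical labels."""

    subject_id: str
    timeseries: np.ndarray  # n_nodes x n_volumes
    outcome: str  # "good" (CPC 1-2) or "poor" (CPC 3-5)
    eeg_category: int  # 1..5
    arrest_to_mri_hours: float
    hospital: str
    comatose_during_mri: bool
    pupils_ssep_absent: bool  # bilateral fixed pupils and/or absent SSEPs
    eeg_class: str  # guideline EEG class: "good" / "poor" / "indifferent"

    def __post_init__(self) -> None:
        ts = np.asarray(self.timeseries, dtype=float)
        if ts.ndim != 2:
            raise ValueError("timeseries must be 2-D (nodes x volumes)")
        if not np.isfinite(ts).all():
            raise ValueError("timeseries contains missing/non-finite values")
        if self.outcome not in ("good", "poor"):
            raise ValueError("outcome must be 'good' or 'poor'")
        if self.eeg_category not in EEG_CATEGORIES:
            raise ValueError("eeg_category must be in 1..5")
        self.timeseries = ts


def _module_assignment(n_nodes: int, n_modules: int) -> np.ndarray:
    """Assign nodes to modules in contiguous, near-equal blocks."""
    blocks = np.array_split(np.arange(n_nodes), n_modules)
    lab = np.empty(n_nodes, dtype=int)
    for m, b in enumerate(blocks):
        lab[b] = m
    return lab


def build_block_covariance(
    n_nodes: int,
    n_modules: int,
    rho_within: float,
    rho_between: float,
    coupling: float,
) -> np.ndarray:
    """Modular block covariance: unit diagonal, ``coupling * rho_within``
    inside modules and ``coupling * rho_between`` between modules.

    Raises ``ValueError`` if the resulting matrix is not positive
    semi-definite (an invalid rho/coupling combination).
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be positive")
    if not (1 <= n_modules <= n_nodes):
        raise ValueError("n_modules must be in [1, n_nodes]")
    if not (0.0 <= coupling):
        raise ValueError("coupling must be non-negative")
    lab = _module_assignment(n_nodes, n_modules)
    same = lab[:, None] == lab[None, :]
    sigma = np.where(same, coupling * rho_within, coupling * rho_between)
    np.fill_diagonal(sigma, 1.0)
    min_eig = float(np.linalg.eigvalsh(sigma)[0])
    if min_eig < -1e-10:
        raise ValueError(
            f"covariance not positive semi-definite (min eigenvalue {min_eig:.3g}); "
            "invalid rho/coupling combination"
        )
    return sigma


def sample_subject(
    covariance: np.ndarray,
    n_volumes: int,
    noise_sd: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw one N x T series from N(0, covariance) plus i.i.d. Gaussian noise.

    The same seed always reproduces the identical table.
    """
    if n_volumes < 3:
        raise ValueError("n_volumes must be >= 3 (correlation undefined below)")
    cov = np.asarray(covariance, dtype=float)
    n = cov.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # Cholesky with a tiny jitter so exactly-PSD matrices (e.g. coupling
    # parameterizations at the PSD boundary) factor cleanly.
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    ts = chol @ rng.standard_normal((n, n_volumes))
    if noise_sd > 0:
        ts = ts + noise_sd * rng.standard_normal((n, n_volumes))
    return ts


def _draw_eeg_class(rng: np.random.Generator, eeg_category: int) -> str:
    """Guideline EEG class from the 5-way category.

    Continuous activity maps to the favourable guideline class most of the
    time (continuous pattern established early); suppressed patterns map to
    the unfavourable class; everything else is indifferent.
    """
    if eeg_category == 3:
        return "good" if rng.random() < 0.7 else "indifferent"
    if eeg_category in (1, 2):
        return "poor" if rng.random() < 0.7 else "indifferent"
    return "indifferent"


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate the full cohort deterministically from ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cov_good = build_block_covariance(
        config.n_nodes, config.n_modules, config.rho_within,
        config.rho_between, config.coupling_good,
    )
    cov_poor = build_block_covariance(
        config.n_nodes, config.n_modules, config.rho_within,
        config.rho_between, config.coupling_poor,
    )
    records: list[SubjectRecord] = []
    n_total = config.n_good + config.n_poor
    width = len(str(n_total))
    for i in range(n_total):
        good = i < config.n_good
        cov = cov_good if good else cov_poor
        ts = sample_subject(cov, config.n_volumes, config.noise_sd, rng)
        eeg_probs = config.eeg_probs_good if good else config.eeg_probs_poor
        eeg_cat = int(rng.choice(EEG_CATEGORIES, p=np.asarray(eeg_probs, dtype=float)))
        mu, sd = config.arrest_to_mri_good if good else config.arrest_to_mri_poor
        hours = float(max(1.0, rng.normal(mu, sd)))
        p_com = config.p_comatose_good if good else config.p_comatose_poor
        p_pup = config.p_pupils_ssep_good if good else config.p_pupils_ssep_poor
        records.append(
            SubjectRecord(
                subject_id=f"sub-{i + 1:0{width}d}",
                timeseries=ts,
                outcome="good" if good else "poor",
                eeg_category=eeg_cat,
                arrest_to_mri_hours=hours,
                hospital=str(rng.choice(config.hospitals)),
                comatose_during_mri=bool(rng.random() < p_com),
                pupils_ssep_absent=bool(rng.random() < p_pup),
                eeg_class=_draw_eeg_class(rng, eeg_cat),
            )
        )
    return records


def cohort_metadata_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Tabulate everything except the time series, one row per subject."""
    rows = []
    for r in records:
        d = asdict(r)
        d.pop("timeseries")
        rows.append(d)
    return pd.DataFrame(rows)
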