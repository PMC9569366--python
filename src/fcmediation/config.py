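"""Cohort configuration.

A :class:`CohortConfig` fully determines a synthetic cohort: the same config and
seed always produce the same subjects, signals, and scores.  Configs round-trip
through YAML so pipeline runs are reproducible from a single text file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


#: (network, hemisphere, parcel count) triples; 8 networks per hemisphere.
DEFAULT_NETWORK_LAYOUT: list[tuple[str, str, int]] = [
    ("salience_ventral_attention", "left", 6),
    ("dorsal_attention", "left", 6),
    ("frontoparietal_control", "left", 7),
    ("default_mode", "left", 8),
    ("temporoparietal", "left", 5),
    ("somatomotor", "left", 8),
    ("reward", "left", 4),
    ("other", "left", 6),
    ("salience_ventral_attention", "right", 6),
    ("dorsal_attention", "right", 6),
    ("frontoparietal_control", "right", 7),
    ("default_mode", "right", 8),
    ("temporoparietal", "right", 5),
    ("somatomotor", "right", 8),
    ("reward", "right", 4),
    ("other", "right", 6),
]

#: Religious belief items (5-point ordinal, 1 = "not at all" ... 5 = "completely").
RELIGIOUS_ITEMS = [f"belief_r{i}" for i in range(1, 8)]
#: Family-values (religion-independent) belief items, same scale.
FAMILY_ITEMS = [f"belief_f{i}" for i in range(1, 4)]
BELIEF_ITEMS = RELIGIOUS_ITEMS + FAMILY_ITEMS


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Effect-size knobs use the classic mediation notation: ``path_a_effect`` is
    the standardized belief -> mediator slope, ``path_b_effect`` the
    mediator -> score slope, ``path_cprime_effect`` the direct belief -> score
    slope, and ``moderation_effect`` the belief x mediator interaction slope.
    ``belief_topology_d`` is the target Cohen's d (belief level 5 vs level 1)
    planted on the targeted network's within-network connectivity.
    """

    n_subjects: int = 200
    n_parcels: int = 100
    n_timepoints: int = 200
    n_runs_per_subject: int = 2
    network_layout: list = field(
        default_factory=lambda: [list(t) for t in DEFAULT_NETWORK_LAYOUT]
    )
    rho_within: float = 0.35
    rho_between: float = 0.10
    # Target of the planted topology effect.
    belief_topology_d: float = 0.3
    target_belief: str = "belief_r2"
    target_network: str = "frontoparietal_control"
    target_hemisphere: str = "right"
    # Between-subject SD of the true within-network correlation (the dispersion
    # the planted d is defined against).
    subject_rho_sd: float = 0.06
    # Mediation / moderation knobs (standardized scales).
    path_a_effect: float = -0.15
    path_b_effect: float = 0.15
    path_cprime_effect: float = -0.10
    moderation_effect: float = -0.08
    # Residual SD of the standardized score; None means "auto": choose so the
    # standardized score has unit variance (planted betas are then exact
    # population standardized coefficients).
    noise_sd: Optional[float] = None
    # Covariate -> standardized score effect (positive income effect mirrors
    # the positive income-score association the analysis expects to recover).
    income_score_effect: float = 0.10
    # Ordinal-belief latent loadings on standardized income / education.
    income_belief_loading: float = -0.15
    education_belief_loading: float = -0.15
    religiosity_loading: float = 0.60
    n_sites: int = 5
    # Extra white-noise SD added to one run so run selection is non-trivial.
    noisy_run_extra_sd: float = 0.75
    # Cognitive score scale: median ~97, IQR ~19 for the Flanker-like task.
    score_center: float = 97.0
    score_scale: float = 19.0 / 1.349
    seed: int = 0

    def validate(self) -> "CohortConfig":
        pos_int = {
            "n_subjects": self.n_subjects,
            "n_parcels": self.n_parcels,
            "n_timepoints": self.n_timepoints,
            "n_runs_per_subject": self.n_runs_per_subject,
            "n_sites": self.n_sites,
        }
        for name, v in pos_int.items():
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if not (0.0 <= self.rho_within < 1.0):
            raise ConfigError(f"rho_within must be in [0, 1), got {self.rho_within!r}")
        degenerate_independent = self.rho_between == self.rho_within == 0.0
        if not degenerate_independent and not (0.0 <= self.rho_between < self.rho_within):
            raise ConfigError(
                "rho_between must be in [0, rho_within); got "
                f"rho_between={self.rho_between!r}, rho_within={self.rho_within!r}"
            )
        for name in (
            "belief_topology_d",
            "path_a_effect",
            "path_b_effect",
            "path_cprime_effect",
            "moderation_effect",
            "income_score_effect",
        ):
            v = float(getattr(self, name))
            if not (v == v and abs(v) < 1e6):  # finite
                raise ConfigError(f"{name} must be finite, got {v!r}")
        if self.noise_sd is not None and not self.noise_sd > 0:
            raise ConfigError(f"noise_sd must be positive or None, got {self.noise_sd!r}")
        if self.subject_rho_sd <= 0:
            raise ConfigError(f"subject_rho_sd must be positive, got {self.subject_rho_sd!r}")
        counts = sum(int(c) for _, _, c in self.network_layout)
        if counts != self.n_parcels:
            raise ConfigError(
                f"network_layout parcel counts sum to {counts}, expected n_parcels={self.n_parcels}"
            )
        if self.target_belief not in BELIEF_ITEMS:
            raise ConfigError(f"target_belief {self.target_belief!r} is not a belief item")
        names = {(n, h) for n, h, _ in self.network_layout}
        if (self.target_network, self.target_hemisphere) not in names:
            raise ConfigError(
                f"target network {(self.target_network, self.target_hemisphere)!r} "
                "not present in network_layout"
            )
        return self

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.network_layout = [list(t) for t in cfg.network_layout]
        return cfg.validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(d)
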