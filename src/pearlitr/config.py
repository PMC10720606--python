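"""Run configuration: one serializable object controlling the whole pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Callable

import yaml

from .solver import SolverOptions

__all__ = ["NuisanceConfig", "LambdaConfig", "PearlConfig", "config_hash"]


@dataclass
class NuisanceConfig:
    """How the propensity and outcome nuisances are estimated.

    ``propensity_fn`` / ``outcome_fns`` override the fitted estimators with
    user-supplied functions (e.g. simulation oracles or fixed misspecified
    models); they are excluded from serialization.
    """

    propensity_method: str = "screened_kernel"
    outcome_method: str = "screened_kernel"
    trim: tuple[float, float] = (0.1, 0.9)
    screen_d: int | None = None
    cv: int = 3
    min_per_arm: int = 10
    propensity_fn: Callable | None = None
    outcome_fns: tuple[Callable, Callable] | None = None


@dataclass
class LambdaConfig:
    """Cross-validated penalty-level selection controls.

    ``fixed`` bypasses cross-validation with a caller-chosen penalty level
    (used in controlled experiments and degenerate-design tests).
    """

    grid_size: int = 50
    cv_folds: int = 5
    grid_eps: float = 0.01
    cv_tol: float = 1e-7
    cv_max_iter: int = 2000
    fixed: float | None = None


@dataclass
class PearlConfig:
    """Everything needed to reproduce a run, besides the data."""

    K: int = 2
    seed: int = 0
    alpha: float = 0.05
    fdr: bool = False
    nuisance: NuisanceConfig = field(default_factory=NuisanceConfig)
    solver: SolverOptions = field(default_factory=SolverOptions)
    lam: LambdaConfig = field(default_factory=LambdaConfig)
    lam_tilde: LambdaConfig = field(default_factory=LambdaConfig)

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        lo, hi = self.nuisance.trim
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("trim bounds must satisfy 0 < lo < hi < 1")

    def cv_solver_options(self, lam_cfg: LambdaConfig) -> SolverOptions:
        """Looser solver controls used inside penalty cross-validation."""
        return SolverOptions(
            tol=lam_cfg.cv_tol, max_iter=lam_cfg.cv_max_iter,
            kkt_tol=self.solver.kkt_tol,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        # callables are not serializable run configuration
        d["nuisance"].pop("propensity_fn", None)
        d["nuisance"].pop("outcome_fns", None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PearlConfig":
        d = dict(d)
        if "nuisance" in d:
            nd = dict(d["nuisance"])
            if "trim" in nd:
                nd["trim"] = tuple(nd["trim"])
            d["nuisance"] = NuisanceConfig(**nd)
        if "solver" in d:
            d["solver"] = SolverOptions(**d["solver"])
        for key in ("lam", "lam_tilde"):
            if key in d:
                d[key] = LambdaConfig(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PearlConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def config_hash(config: PearlConfig) -> str:
    """SHA-256 over the canonical JSON serialization of the configuration."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
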