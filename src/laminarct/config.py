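"""Run configuration: validation, YAML round-trip, deterministic seeding."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .errors import SpecError
from .synthetic import CohortSpec, RibbonSpec

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a full synthetic analysis run needs.

    A single global ``seed`` deterministically spawns per-stage child seeds
    (cohort generation, per-subject phantoms, Monte-Carlo power), so one
    integer reproduces the entire run.
    """

    ribbon: dict = field(default_factory=dict)       # RibbonSpec overrides
    cohort: dict = field(default_factory=dict)       # CohortSpec overrides
    n_samples: int = 101
    pairing_rule: str = "nearest"
    alpha: float = 0.05
    bonferroni_m: int = 6
    variance_center: str = "median"
    outdir: str = "laminarct_run"
    seed: int = 0

    def __post_init__(self):
        # validate sub-specs eagerly so bad configs fail before any compute
        self.ribbon_spec()
        self.cohort_spec()
        if self.n_samples < 5:
            raise SpecError("n_samples must be >= 5 for a quartic fit")
        if self.pairing_rule not in ("nearest", "all_pairs"):
            raise SpecError(f"unknown pairing rule {self.pairing_rule!r}")
        if not (0 < self.alpha < 1):
            raise SpecError("alpha must lie in (0, 1)")

    def ribbon_spec(self, **overrides) -> RibbonSpec:
        return RibbonSpec(**{**self.ribbon, **overrides})

    def cohort_spec(self, **overrides) -> CohortSpec:
        kw = dict(self.cohort)
        kw.setdefault("seed", self.seed)
        kw.update(overrides)
        if "n_per_group" in kw:
            kw["n_per_group"] = tuple(kw["n_per_group"])
        return CohortSpec(**kw)

    def child_seeds(self, n: int) -> list:
        """Deterministic per-stage seeds spawned from the global seed."""
        ss = np.random.SeedSequence(self.seed)
        return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = asdict(self)
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
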