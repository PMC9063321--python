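"""Pipeline configuration with provenance defaults.

All stage parameters live in one dataclass so a run can be resumed or
audited from its recorded configuration.  Defaults: 22-TR tapered window
(Gaussian sigma 3 TRs), tau = 2 x window length = 44, UMAP n_neighbors 25 /
min_dist 0.75 averaged over R = 25 runs, K = 10 exemplars, n = 25 lifting
neighbors, M = 10 meta-states, 5 snapshot states, k-means with 2000
iterations and 250 restarts (500 for weight vectors).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

from .errors import InvalidParameterError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # dFNC stage
    window_len: int = 22
    taper_sigma: float = 3.0
    step: int = 1
    fisher_z: bool = False
    # snapshot baseline
    k_snap: int = 5
    snap_restarts: int = 250
    # embedding
    n_neighbors: int = 25
    min_dist: float = 0.75
    n_runs: int = 25
    align_runs: bool = False
    # exemplars
    tau: int | None = None  # defaults to 2 * window_len
    K: int = 10
    exemplar_restarts: int = 250
    # lifting
    n_lift: int = 25
    # representation
    ri_mode: str = "argmax"
    M: int = 10
    meta_restarts: int = 500
    # shared
    kmeans_max_iter: int = 2000
    correction: str = "bh"
    seed: int = 0

    def __post_init__(self):
        if self.tau is None:
            self.tau = 2 * self.window_len
        if self.window_len < 3:
            raise InvalidParameterError("window_len must be >= 3")
        if self.tau < 2:
            raise InvalidParameterError("tau must be >= 2")
        if self.ri_mode not in ("argmax", "meancorr"):
            raise InvalidParameterError("ri_mode must be 'argmax' or 'meancorr'")
        if self.correction not in ("bh", "bonferroni"):
            raise InvalidParameterError("correction must be 'bh' or 'bonferroni'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if math.isinf(d["taper_sigma"]):
            d["taper_sigma"] = "inf"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("taper_sigma") == "inf":
            d["taper_sigma"] = math.inf
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))
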