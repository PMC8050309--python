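"""The Sensorgram container: the universal exchange object of the package.

A sensorgram is a set of biosensor response curves sharing one time base,
with per-curve metadata (inhibitor concentration, flow velocity, labels, ...)
and a provenance block recording how the curves were produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["Sensorgram"]


@dataclass
class Sensorgram:
    """Time/response curve set.

    time     : (nt,) strictly increasing, seconds
    response : (nt, ncurves) response units (RU)
    metadata : one dict per curve (keys like ``A``, ``flow_velocity``,
               ``label``, ``Rmax``, ``Mr_B``)
    provenance: generator name, seed and parameters
    """

    time: np.ndarray
    response: np.ndarray
    metadata: list[dict[str, Any]] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.response.ndim == 1:
            self.response = self.response[:, None]
        if self.time.ndim != 1 or self.time.size != self.response.shape[0]:
            raise ValueError("time and response shapes are inconsistent")
        if np.any(np.diff(self.time) <= 0):
            bad = int(np.flatnonzero(np.diff(self.time) <= 0)[0]) + 1
            raise ValueError(f"time must be strictly increasing (row {bad})")
        if not self.metadata:
            self.metadata = [{} for _ in range(self.n_curves)]
        if len(self.metadata) != self.n_curves:
            raise ValueError("one metadata dict per curve is required")

    @property
    def n_curves(self) -> int:
        return self.response.shape[1]

    def labels(self) -> list[str]:
        return [str(m.get("label", f"c{i}")) for i, m in enumerate(self.metadata)]

    def curve(self, i: int) -> np.ndarray:
        return self.response[:, i]

    def select(self, indices) -> "Sensorgram":
        indices = list(indices)
        return Sensorgram(
            time=self.time.copy(),
            response=self.response[:, indices].copy(),
            metadata=[dict(self.metadata[i]) for i in indices],
            provenance=dict(self.provenance),
        )

    def with_noise(self, rms: float, rng: np.random.Generator) -> "Sensorgram":
        """Return a copy with additive Gaussian baseline noise of given RMS (RU)."""
        noisy = self.response + rng.normal(0.0, rms, size=self.response.shape)
        prov = dict(self.provenance)
        prov["noise_rms"] = rms
        return Sensorgram(self.time.copy(), noisy, [dict(m) for m in self.metadata], prov)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.response, index=pd.Index(self.time, name="time"),
                            columns=self.labels())

    @staticmethod
    def concat(parts: list["Sensorgram"]) -> "Sensorgram":
        """Join curve sets sharing an identical time base."""
        t0 = parts[0].time
        for p in parts[1:]:
            if p.time.shape != t0.shape or not np.allclose(p.time, t0):
                raise ValueError("curve sets must share one time base")
        return Sensorgram(
            time=t0.copy(),
            response=np.hstack([p.response for p in parts]),
            metadata=[dict(m) for p in parts for m in p.metadata],
            provenance=dict(parts[0].provenance),
        )
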