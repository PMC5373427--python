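"""Serializable run reports.

A :class:`RunReport` captures everything needed to reproduce an estimation
run: the input descriptor, all parameters, the seed, the per-method
estimates (with replicate histograms when resampling was used) and any
warnings raised along the way.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Any

from . import __version__
from .estimators import ClusterCountEstimate


def _jsonable(obj: Any) -> Any:
    """Coerce numpy scalars/arrays and dataclass leaves to JSON types."""
    if hasattr(obj, "item") and not isinstance(obj, (list, dict)):
        try:
            return obj.item()
        except (ValueError, AttributeError):
            pass
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class RunReport:
    """Complete record of one estimation run."""

    input_descriptor: str
    parameters: dict[str, Any]
    estimates: list[dict[str, Any]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    seed: int | None = None
    version: str = __version__

    def add_estimate(self, estimate: ClusterCountEstimate) -> None:
        self.estimates.append(
            {
                "method": estimate.method,
                "k_hat": int(estimate.k_hat),
                "diagnostics": _jsonable(estimate.diagnostics),
            }
        )

    def add_warning(self, message: str) -> None:
        self.warnings.append(message)

    def to_dict(self) -> dict[str, Any]:
        return _jsonable(asdict(self))

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_dict(cls, payload: dict[str, Any]) -> "RunReport":
        return cls(**payload)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls.from_dict(json.loads(text))
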