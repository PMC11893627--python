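"""Pipeline-level configuration with YAML loading and validation."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import yaml

from .preprocess import DEFAULT_ROI_SIZES, NORMED_THRESHOLD
from .segment import BINARIZE_THRESHOLD, NetworkConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything the CLI needs to run the pipeline end to end."""

    histogram_threshold: float = NORMED_THRESHOLD
    binarize_threshold: float = BINARIZE_THRESHOLD
    roi_sizes: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_ROI_SIZES)
    )
    network: NetworkConfig = field(default_factory=NetworkConfig)
    pixel_spacing_mm: float | None = None
    seed: int = 0

    def validate(self) -> None:
        for name, t in (
            ("histogram_threshold", self.histogram_threshold),
            ("binarize_threshold", self.binarize_threshold),
        ):
            if not 0.0 < t < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {t}")
        self.network.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        net = raw.pop("network", {})
        if "input_hw" in net:
            net["input_hw"] = tuple(net["input_hw"])
        if "branch_kernels" in net:
            net["branch_kernels"] = tuple(net["branch_kernels"])
        roi_sizes = {
            k: tuple(v) for k, v in raw.pop("roi_sizes", DEFAULT_ROI_SIZES).items()
        }
        cfg = cls(network=NetworkConfig(**net), roi_sizes=roi_sizes, **raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)
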