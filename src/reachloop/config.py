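"""Analysis configuration shared across pipeline stages.

All durations are in seconds. Defaults encode the conventions used
throughout the analyses: a 50 ms Gaussian kernel for visualization-grade
rate estimation, a 25 ms kernel for decoding-grade rates and hand
velocity, 1 ms spike-count bins, a 2 ms decoder feature clock with 15
taps (28 ms of history), an 800 ms / 8-bump raised-cosine event window
for the GLM, a 0.5–2.0 s entrainment analysis window within each
stimulation epoch, and q < 0.05 Benjamini–Hochberg significance.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass
class AnalysisConfig:
    rate_kernel_sigma_s: float = 0.050
    decode_kernel_sigma_s: float = 0.025
    bin_width_s: float = 0.001
    decoder_feature_dt_s: float = 0.002
    decoder_n_taps: int = 15
    glm_window_s: float = 0.8
    glm_n_basis: int = 8
    entrain_window_s: tuple[float, float] = (0.5, 2.0)
    fdr_alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "rate_kernel_sigma_s",
            "decode_kernel_sigma_s",
            "bin_width_s",
            "decoder_feature_dt_s",
            "glm_window_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.decoder_n_taps < 1 or self.glm_n_basis < 2:
            raise ValueError("decoder_n_taps >= 1 and glm_n_basis >= 2 required")
        lo, hi = self.entrain_window_s
        if not (0 <= lo < hi):
            raise ValueError("entrain_window_s must satisfy 0 <= lo < hi")
        if not (0.0 < self.fdr_alpha < 1.0):
            raise ValueError("fdr_alpha must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown AnalysisConfig fields: {sorted(unknown)}")
        d = dict(d)
        if "entrain_window_s" in d:
            d["entrain_window_s"] = tuple(d["entrain_window_s"])
        return cls(**d)

    def to_dict(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        out["entrain_window_s"] = list(self.entrain_window_s)
        return out
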