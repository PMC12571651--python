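"""Default hyperparameter configuration shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AdapterConfig:
    """Dimensions and weights of the adapter stack.

    Attributes
    ----------
    h : hidden dimension of the encoders (must be divisible by 4: the
        reversible adapter splits the embedding in half and projects each
        half down to a quarter).
    d : bottleneck dimension of the language/task adapters.
    use_bias : whether the affine maps carry bias terms.
    lambda1 : weight of the local alignment loss in the total loss.
    mask_rate : fraction of image patches masked out before encoding.
    """

    h: int = 768
    d: int = 64
    use_bias: bool = True
    lambda1: float = 0.8
    mask_rate: float = 0.75

    def __post_init__(self):
        if self.h <= 0 or self.h % 4 != 0:
            raise ValueError(f"h must be a positive multiple of 4, got {self.h}")
        if not (0 < self.d < self.h):
            raise ValueError(f"d must satisfy 0 < d < h, got d={self.d}, h={self.h}")
        if self.lambda1 < 0:
            raise ValueError(f"lambda1 must be nonnegative, got {self.lambda1}")
        if not (0 <= self.mask_rate < 1):
            raise ValueError(f"mask_rate must lie in [0, 1), got {self.mask_rate}")


@dataclass
class TrainConfig:
    """Training-loop settings; defaults follow the reference configuration."""

    batch_size: int = 32
    lr_language_adapter: float = 5e-5
    lr_task_adapter: float = 1e-4
    lr_reversible_adapter: float = 1e-4
    weight_decay: float = 1e-4
    epochs: int = 1
    max_steps: int | None = None
    seed: int = 0
    objective: str = "paper"  # "paper" (positives-only) or "contrastive"
    temperature: float = 0.1
    lambda1: float = 0.8
    mode: str = "pretrain"  # or "downstream"

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        for name in ("lr_language_adapter", "lr_task_adapter", "lr_reversible_adapter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.objective not in ("paper", "contrastive"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.mode not in ("pretrain", "downstream"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ModelConfig:
    """Encoder backbone geometry (small configurable transformers)."""

    h: int = 768
    depth: int = 2
    n_heads: int = 2
    d: int = 64
    ffn_mult: int = 2
    vocab_size: int = 4096
    max_text_len: int = 128
    patch_side: int = 16
    image_side: int = 224
    n_locals: int = 4
    use_bias: bool = True
    seed: int = 0

    @property
    def patch_dim(self) -> int:
        return self.patch_side * self.patch_side

    @property
    def n_patches(self) -> int:
        g = self.image_side // self.patch_side
        return g * g

    def adapter_config(self) -> AdapterConfig:
        return AdapterConfig(h=self.h, d=self.d, use_bias=self.use_bias)


TEST_MODEL_PROFILE = dict(h=32, depth=2, n_heads=2, d=8, vocab_size=512)
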