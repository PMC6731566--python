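"""Training and run configuration."""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

from .errors import ConfigError


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings for a single network or a transfer run.

    ``source_ratio`` is the fraction of source-domain documents used in
    phase-1 training (a transfer hyperparameter, document-level subsampling);
    dropout 0.5 is applied before the BiLSTM and fully-connected layers
    during training only.
    """

    hidden_size: int = 300
    fc_size: int = 600
    peephole: bool = True
    optimizer: str = "adam"       # "adam" | "sgd"
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 30
    patience: int = 5
    early_stopping: bool = True
    dropout: float = 0.5
    clip_norm: float = 5.0
    shuffle: bool = True
    min_count: int = 1
    # transfer-specific
    source_ratio: float = 1.0
    epochs_source: int | None = None     # None -> epochs
    source_dev_fraction: float = 0.1     # phase-1 early-stopping split
    freeze_shared_phase3: bool = False   # optional freeze schedule
    share_crf: bool = False              # experimental CRF-transition sharing

    def __post_init__(self):
        if not (0.0 <= self.source_ratio <= 1.0):
            raise ConfigError("source_ratio must lie in [0, 1]")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError("dropout must lie in [0, 1)")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")
        if self.epochs < 0 or self.batch_size < 1:
            raise ConfigError("epochs must be >= 0 and batch_size >= 1")

    def with_(self, **kw) -> "TrainConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)
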