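"""Run configuration: every pipeline tunable with its documented default,
round-tripping losslessly to YAML.  CLI flags override file values, and
each run writes its resolved configuration next to its outputs for
provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class RunConfig:
    # paths
    participants_csv: str | None = None
    transcripts_dir: str | None = None
    audio_dir: str | None = None
    lexicon_dir: str | None = None
    output_dir: str | None = None
    # contrast
    contrast: str = "cn_vs_impaired"
    # transcript features
    spurt_gap_s: float = 1.0
    min_gap_s: float = 0.25
    silence_source: str = "tokens"
    # audio preprocessing
    butter_cutoff_hz: float = 7000.0
    butter_order: int = 4
    include_audio: bool = True
    # model training
    n_splits: int = 10
    n_repeats: int = 10
    logit_eps: float = 1e-6
    train_frac: float = 0.70
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def override(self, **kwargs) -> "RunConfig":
        data = asdict(self)
        data.update({k: v for k, v in kwargs.items() if v is not None})
        return RunConfig(**data)
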