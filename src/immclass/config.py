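"""Pipeline configuration: every tunable threshold in one structure.

Values can be loaded from / dumped to YAML so a run is fully described
by (inputs, config, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace

import yaml

from .align import ScoringScheme


@dataclass(frozen=True)
class PipelineConfig:
    # scoring
    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    # domain scan
    min_normalized: float = 0.3
    max_copies: int = 4
    # Arg/Lys-rich detector
    rk_window: int = 20
    rk_min_fraction: float = 0.4
    rk_min_length: int = 30
    # Tat signal
    tat_n_window: int = 80
    h_min_len: int = 8
    h_min_mean: float = 1.5
    cleave_window: int = 30
    allow_kr_variants: bool = False
    # ER / NLS
    er_n_window: int = 30
    mono_window: int = 6
    mono_min_basic: int = 4
    bi_spacer_min: int = 9
    bi_spacer_max: int = 12
    # orthology / naming
    id_threshold: float = 50.0
    identity_denominator: str = "aligned_columns"
    organism_prefix: str = "Os"

    @property
    def scheme(self) -> ScoringScheme:
        return ScoringScheme(
            matrix_name=self.matrix_name,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
        )

    @property
    def bi_spacer(self) -> range:
        return range(self.bi_spacer_min, self.bi_spacer_max + 1)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
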