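"""Run configuration: every tunable default in one serializable object.

A single master seed drives all randomness; per-stage seeds are derived
with a documented counter scheme (``stage_seed``) so each pipeline stage
gets an independent, reproducible stream.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "stage_seed", "STAGES"]

#: stage → counter index for per-stage seed derivation
STAGES = {"simulate": 0, "sample": 1, "bootstrap": 2, "segment": 3, "cohort": 4}


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive the stage's RNG seed from the master seed: the first state
    word of ``SeedSequence([master_seed, STAGES[stage]])``, reduced below
    2**31."""
    k = STAGES[stage]
    return int(np.random.SeedSequence([master_seed, k]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Effective parameters of a QC run; embedded verbatim in every report."""

    # ion-image extraction
    mz_tol: float = 0.25
    reducer: str = "sum"
    # mixed-pixel scoring
    low_pct: float = 3.0
    high_pct: float = 97.0
    ratio: float = 0.70
    rescale_after_clip: bool = False
    # mask fallback
    tic_mask_quantile: float = 0.2
    # peak picking
    min_snr: float = 1.0
    max_peaks: int = 10_000
    noise_window: float = 50.0
    smooth_sigma: float = 0.15
    merge_tol: float = 0.1
    envelope_tol: float = 0.15
    # spectral quality
    n_sampled: int = 100
    snr_cutoff: float = 3.0
    mz_cutoff_1: float = 1500.0
    mz_cutoff_2: float = 2000.0
    n_boot: int = 1000
    ci_level: float = 0.95
    # intensity CV
    cv_min_snr: float = 3.0
    cv_match_tol: float = 0.25
    # segmentation
    align_tol: float = 0.3
    integration_tol: float = 0.25
    denoise_window: int = 3
    segment_min_snr: float = 3.0
    max_depth: int = 4
    n_init: int = 10
    # master seed
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        try:
            data = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            line = f" at line {mark.line + 1}" if mark is not None else ""
            raise ValueError(f"malformed YAML in {path}{line}: {exc}") from exc
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must contain a mapping")
        known = {f.name for f in fields(cls)}
        bad = sorted(set(data) - known)
        if bad:
            raise ValueError(f"unknown config keys in {path}: {', '.join(bad)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
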