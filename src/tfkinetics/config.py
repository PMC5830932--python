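"""Run configuration: one YAML-serializable object holding every threshold.

Defaults equal the analysis constants the pipeline is defined by (windows
+/-3 kb / +/-100 bp / +/-25 kb / 200 bp; fold change > 2 at p < 0.01 with an
FPKM >= 1 filter; the > 10-fold stringent stratum; footprint widths 11-25 bp
with 35-bp shoulders at 1% FDR; LMR band 10-50% with >= 4 CpGs). The master
seed fans out to per-stage seeds by fixed offsets.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "validate_config"]

#: fixed per-stage seed offsets from the master seed
STAGE_SEED_OFFSETS = {
    "genome": 0,
    "noise": 1,
    "footprints": 2,
    "stem": 3,
    "dependency": 4,
}


def _defaults() -> dict:
    return {
        "timepoints": ["0h", "24h", "72h", "proB"],
        "include_6h": False,
        "synthetic": {
            "enabled": True,
            "n_chroms": 1,
            "chrom_len": 2_000_000,
            "n_genes": 200,
            "n_sites": 500,
            "n_replicates": 2,
            "lmr_prob": 0.6,
        },
        "noise": {
            "peak_dropout_prob": 0.05,
            "signal_depth": 30.0,
            "background_rate": 0.5,
            "meth_coverage": 30.0,
            "expr_dispersion": 0.25,
        },
        "peaks": {"min_overlap_bp": 1, "merge_gap_bp": 0, "replicate_rule": "pooled"},
        "signal": {
            "window_bp": 3000,
            "bin_bp": 50,
            "center_bp": 500,
            "gain_fold": 2.0,
            "min_rpkm": "auto",
        },
        "methylation": {
            "min_coverage": 5,
            "low_band": [0.10, 0.50],
            "min_cpgs": 4,
            "max_gap_bp": 250,
            "window_bp": 100,
            "association_bp": 100,
        },
        "footprints": {
            "widths": list(range(11, 26, 2)),
            "shoulder_bp": 35,
            "fdr": 0.01,
            "n_shuffles": 20,
            "cooccurrence_window_bp": 200,
        },
        "expression": {
            "fc_threshold": 2.0,
            "p_threshold": 0.01,
            "min_fpkm": 1.0,
            "cutoff_fold": 10.0,
            "window_kb": 25.0,
            "stem": {"c": 2, "n_model_profiles": 6, "n_permutations": 100},
        },
        "dependency": {
            "n_secondary": 400,
            "cobound_frac": 0.5,
            "dependent_frac_cobound": 0.5,
            "preaccessible_frac_independent": 0.9,
            "cooccupancy_window_bp": 200,
        },
        "inputs": {},
    }


@dataclass
class RunConfig:
    """All pipeline settings; ``seed`` is the master seed."""

    seed: int = 1
    settings: dict = field(default_factory=_defaults)

    def __post_init__(self):
        base = _defaults()
        self.settings = _deep_merge(base, self.settings or {})

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) * 7 + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)

    def __getitem__(self, key: str):
        return self.settings[key]

    def to_yaml(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {"seed": int(self.seed), "settings": copy.deepcopy(self.settings)}
        path.write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise ValueError(f"{path}: not a mapping")
        return cls(seed=payload.get("seed", 1), settings=payload.get("settings", {}))


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def validate_config(config: RunConfig) -> list[str]:
    """Collect configuration issues; an empty list means the run may proceed."""
    issues: list[str] = []
    s = config.settings

    def positive(path: str, value, strict=True):
        bad = value <= 0 if strict else value < 0
        if bad:
            issues.append(f"{path} = {value}: must be positive")

    positive("synthetic.chrom_len", s["synthetic"]["chrom_len"])
    positive("synthetic.n_sites", s["synthetic"]["n_sites"])
    positive("signal.window_bp", s["signal"]["window_bp"])
    positive("signal.bin_bp", s["signal"]["bin_bp"])
    if s["signal"]["window_bp"] % s["signal"]["bin_bp"] != 0:
        issues.append("signal.window_bp must be divisible by signal.bin_bp")
    if s["signal"]["gain_fold"] < 1:
        issues.append(f"signal.gain_fold = {s['signal']['gain_fold']}: must be >= 1")
    if not 0 <= s["noise"]["peak_dropout_prob"] <= 1:
        issues.append("noise.peak_dropout_prob must lie in [0, 1]")
    if s["expression"]["fc_threshold"] < 1:
        issues.append("expression.fc_threshold must be >= 1")
    if not 0 < s["expression"]["p_threshold"] < 1:
        issues.append("expression.p_threshold must lie in (0, 1)")
    positive("expression.window_kb", s["expression"]["window_kb"])
    lo, hi = s["methylation"]["low_band"]
    if not 0 <= lo < hi <= 1:
        issues.append(f"methylation.low_band = {(lo, hi)}: need 0 <= lo < hi <= 1")
    if not 0 < s["footprints"]["fdr"] < 1:
        issues.append("footprints.fdr must lie in (0, 1)")
    if any(w <= 0 for w in s["footprints"]["widths"]):
        issues.append("footprints.widths must be positive")
    known_tp = {"0h", "6h", "24h", "72h", "proB"}
    unknown = set(s["timepoints"]) - known_tp
    if unknown:
        issues.append(f"unknown timepoint labels: {sorted(unknown)}")
    for assay, path in (s.get("inputs") or {}).items():
        if path and not Path(path).exists():
            issues.append(f"inputs.{assay}: file not found: {path}")
    if not s["synthetic"]["enabled"] and not s.get("inputs"):
        issues.append("synthetic mode disabled and no inputs supplied")
    return issues
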