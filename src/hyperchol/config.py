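"""Configuration loading and validation.

Default panel, DLCN point table, statin coefficients, percentile reference and
generator settings ship as YAML files inside the package; a user-supplied
pipeline configuration overrides any subset.  Unknown keys are rejected so
typos fail loudly at load time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Mapping, Optional

import yaml

from .dlcn import DEFAULT_POINTS, DLCNPointTable
from .errors import ConfigError
from .lipids import PercentileReference, StatinCoefficientTable
from .pgs import DEFAULT_PGS_THRESHOLD, SNVPanel
from .selection import SelectionCriteria


def _read_packaged_yaml(name: str) -> dict:
    text = resources.files("hyperchol.data").joinpath(name).read_text()
    return yaml.safe_load(text)


def load_default_panel() -> SNVPanel:
    rows = _read_packaged_yaml("panel.yaml")["snv_panel"]
    return SNVPanel.from_rows(rows, expected_size=12)


def load_default_statin_table() -> StatinCoefficientTable:
    data = _read_packaged_yaml("statins.yaml")["statin_coefficients"]
    return StatinCoefficientTable(data)


def load_default_percentile_reference() -> PercentileReference:
    rows = _read_packaged_yaml("percentiles.yaml")["percentile_reference"]
    return PercentileReference.from_rows(rows)


def load_default_dlcn_points() -> DLCNPointTable:
    return DLCNPointTable.from_mapping(_read_packaged_yaml("dlcn_points.yaml"))


def load_default_generator_mapping() -> dict:
    """Generator defaults, with the shared SNV panel merged in."""
    data = _read_packaged_yaml("generator.yaml")
    data.setdefault("snv_panel", _read_packaged_yaml("panel.yaml")["snv_panel"])
    return data


_TOP_LEVEL_KEYS = {
    "seed",
    "selection",
    "lipid",
    "dlcn",
    "pathogenicity",
    "pgs",
    "panel_file",
    "statin_file",
    "percentile_file",
    "dlcn_points_file",
}
_SELECTION_KEYS = {"age_min", "age_max", "ldl_threshold", "window_days"}
_LIPID_KEYS = {"imputation_basis"}
_DLCN_KEYS = {"include_dna"}
_PATHO_KEYS = {"frequency_threshold", "lof_mechanism", "use_pp5_bp6"}
_PGS_KEYS = {"threshold", "missing_policy"}


def _check_keys(section: Mapping, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown configuration keys in {where}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, validated at load time."""

    seed: int = 0
    selection: SelectionCriteria = field(default_factory=SelectionCriteria)
    imputation_basis: str = "max"  # impute from the highest recorded LDL ("max") or index LDL
    include_dna: bool = False
    frequency_threshold: float = 0.001
    lof_mechanism: Dict[str, bool] = field(
        default_factory=lambda: {"LDLR": True, "APOB": False, "PCSK9": False}
    )
    use_pp5_bp6: bool = True
    pgs_threshold: float = DEFAULT_PGS_THRESHOLD
    missing_policy: str = "impute"
    panel: SNVPanel = field(default_factory=load_default_panel)
    statin_table: StatinCoefficientTable = field(default_factory=load_default_statin_table)
    percentile_reference: PercentileReference = field(
        default_factory=load_default_percentile_reference
    )
    dlcn_points: DLCNPointTable = field(default_factory=lambda: DEFAULT_POINTS)

    def __post_init__(self):
        self.selection.validate()
        if self.imputation_basis not in ("max", "index"):
            raise ConfigError(
                f"lipid.imputation_basis must be 'max' or 'index', got {self.imputation_basis!r}"
            )
        if not (0.0 < self.frequency_threshold <= 1.0):
            raise ConfigError(
                f"pathogenicity.frequency_threshold must be in (0, 1], got {self.frequency_threshold}"
            )
        if self.missing_policy not in ("impute", "strict"):
            raise ConfigError(
                f"pgs.missing_policy must be 'impute' or 'strict', got {self.missing_policy!r}"
            )

    @classmethod
    def from_yaml(cls, path: Optional[str] = None) -> "PipelineConfig":
        if path is None:
            return cls()
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"configuration file not found: {path}")
        data = yaml.safe_load(p.read_text()) or {}
        _check_keys(data, _TOP_LEVEL_KEYS, "top level")
        kwargs: dict = {}
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        if "selection" in data:
            sec = data["selection"]
            _check_keys(sec, _SELECTION_KEYS, "selection")
            kwargs["selection"] = SelectionCriteria(
                age_min=float(sec.get("age_min", 18.0)),
                age_max=float(sec.get("age_max", 70.0)),
                ldl_threshold=float(sec.get("ldl_threshold", 155.0)),
                window_days=int(sec.get("window_days", 365)),
            )
        if "lipid" in data:
            _check_keys(data["lipid"], _LIPID_KEYS, "lipid")
            kwargs["imputation_basis"] = data["lipid"].get("imputation_basis", "max")
        if "dlcn" in data:
            _check_keys(data["dlcn"], _DLCN_KEYS, "dlcn")
            kwargs["include_dna"] = bool(data["dlcn"].get("include_dna", False))
        if "pathogenicity" in data:
            sec = data["pathogenicity"]
            _check_keys(sec, _PATHO_KEYS, "pathogenicity")
            if "frequency_threshold" in sec:
                kwargs["frequency_threshold"] = float(sec["frequency_threshold"])
            if "lof_mechanism" in sec:
                kwargs["lof_mechanism"] = {str(k): bool(v) for k, v in sec["lof_mechanism"].items()}
            if "use_pp5_bp6" in sec:
                kwargs["use_pp5_bp6"] = bool(sec["use_pp5_bp6"])
        if "pgs" in data:
            sec = data["pgs"]
            _check_keys(sec, _PGS_KEYS, "pgs")
            if "threshold" in sec:
                kwargs["pgs_threshold"] = float(sec["threshold"])
            if "missing_policy" in sec:
                kwargs["missing_policy"] = sec["missing_policy"]
        for key, loader in (
            ("panel_file", lambda q: SNVPanel.from_rows(yaml.safe_load(q)["snv_panel"])),
            ("statin_file", lambda q: StatinCoefficientTable(yaml.safe_load(q)["statin_coefficients"])),
            (
                "percentile_file",
                lambda q: PercentileReference.from_rows(yaml.safe_load(q)["percentile_reference"]),
            ),
            ("dlcn_points_file", lambda q: DLCNPointTable.from_mapping(yaml.safe_load(q))),
        ):
            if key in data:
                fp = Path(data[key])
                if not fp.exists():
                    raise ConfigError(f"{key}: file not found: {fp}")
                attr = {
                    "panel_file": "panel",
                    "statin_file": "statin_table",
                    "percentile_file": "percentile_reference",
                    "dlcn_points_file": "dlcn_points",
                }[key]
                kwargs[attr] = loader(fp.read_text())
        return cls(**kwargs)

    def hash(self) -> str:
        """Stable hash of the scalar settings (for the run manifest)."""
        payload = {
            "seed": self.seed,
            "selection": {
                "age_min": self.selection.age_min,
                "age_max": self.selection.age_max,
                "ldl_threshold": self.selection.ldl_threshold,
                "window_days": self.selection.window_days,
            },
            "imputation_basis": self.imputation_basis,
            "include_dna": self.include_dna,
            "frequency_threshold": self.frequency_threshold,
            "lof_mechanism": self.lof_mechanism,
            "use_pp5_bp6": self.use_pp5_bp6,
            "pgs_threshold": self.pgs_threshold,
            "missing_policy": self.missing_policy,
            "panel_ids": list(self.panel.ids),
            "panel_weights": [e.weight for e in self.panel.entries],
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()
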