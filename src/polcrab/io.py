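"""Trial-table, calibration and configuration I/O.

Trial tables are long-format CSV, one behaviour per row and one empty
behaviour row for a no-response trial, with header
``crab_id,species,modality,contrast,order,behaviour,onset_s,pre_stim_retreat``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .behaviour import BEHAVIOUR_KINDS, TrialRecord
from .stimulus import ScreenCalibration

TRIAL_COLUMNS = [
    "crab_id",
    "species",
    "modality",
    "contrast",
    "order",
    "behaviour",
    "onset_s",
    "pre_stim_retreat",
]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


class FormatError(ValueError):
    """Header or file-level structure does not match the trial-table dialect."""


class TrialTableError(ValueError):
    """Row-level validation failures; message lists every bad row."""


def _parse_bool(raw: str, row: int, errors: list) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    errors.append(f"row {row}: pre_stim_retreat: cannot parse {raw!r} as boolean")
    return False


def read_trials(path) -> list[TrialRecord]:
    """Read a long-format trial table into typed records.

    Rows sharing (crab_id, species, modality, contrast, order) form one
    trial.  Every validation failure is collected with its row number; any
    failure aborts the read with a :class:`TrialTableError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != TRIAL_COLUMNS:
        raise FormatError(
            f"bad header: expected {','.join(TRIAL_COLUMNS)}, got {','.join(df.columns)}"
        )
    errors: list[str] = []
    parsed = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        rec = {"crab_id": row.crab_id, "species": row.species, "modality": row.modality}
        try:
            rec["contrast"] = float(row.contrast)
        except ValueError:
            errors.append(f"row {i}: contrast: cannot parse {row.contrast!r} as float")
            continue
        try:
            rec["order"] = int(row.order)
            if rec["order"] < 1:
                errors.append(f"row {i}: order: must be >= 1, got {rec['order']}")
                continue
        except ValueError:
            errors.append(f"row {i}: order: cannot parse {row.order!r} as integer")
            continue
        behaviour = str(row.behaviour).strip()
        if behaviour and behaviour not in BEHAVIOUR_KINDS:
            errors.append(f"row {i}: behaviour: unknown kind {behaviour!r}")
            continue
        if behaviour:
            try:
                rec["onset"] = (behaviour, float(row.onset_s))
            except ValueError:
                errors.append(f"row {i}: onset_s: cannot parse {row.onset_s!r} as float")
                continue
        else:
            rec["onset"] = None
        rec["pre_stim_retreat"] = _parse_bool(row.pre_stim_retreat, i, errors)
        parsed.append(rec)
    if errors:
        raise TrialTableError(f"{len(errors)} invalid rows:\n" + "\n".join(errors))

    trials: dict[tuple, TrialRecord] = {}
    for rec in parsed:
        key = (rec["crab_id"], rec["species"], rec["modality"], rec["contrast"], rec["order"])
        if key not in trials:
            trials[key] = TrialRecord(
                crab_id=rec["crab_id"],
                species=rec["species"],
                modality=rec["modality"],
                contrast=rec["contrast"],
                order=rec["order"],
                behaviours=[],
                pre_stimulus_full_retreat=rec["pre_stim_retreat"],
            )
        if rec["onset"] is not None:
            trials[key].behaviours.append(rec["onset"])
        trials[key].pre_stimulus_full_retreat |= rec["pre_stim_retreat"]
    return list(trials.values())


def write_trials(trials, path) -> None:
    """Write records in the long-format trial-table dialect."""
    rows = []
    for t in trials:
        base = dict(
            crab_id=t.crab_id,
            species=t.species,
            modality=t.modality,
            contrast=t.contrast,
            order=t.order,
            pre_stim_retreat=t.pre_stimulus_full_retreat,
        )
        if t.behaviours:
            for kind, onset in t.behaviours:
                rows.append({**base, "behaviour": kind, "onset_s": onset})
        else:
            rows.append({**base, "behaviour": "", "onset_s": ""})
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def read_calibration(path) -> ScreenCalibration:
    """Read a screen-calibration CSV (header ``grey,radiance,dop``)."""
    df = pd.read_csv(path)
    required = {"grey", "radiance"}
    if not required <= set(df.columns):
        raise FormatError(f"calibration CSV needs columns {sorted(required)}, got {list(df.columns)}")
    return ScreenCalibration.from_frame(df)


# ---------------------------------------------------------------------------
# Run configuration

class PolarimetryConfig(BaseModel):
    layout: list[list[int]] = [[90, 45], [135, 0]]
    bit_depth: int = 12
    saturation_margin: int = 0
    floor_threshold: float = 1.0


class BehaviourConfig(BaseModel):
    window: tuple[float, float] | None = None
    quadratic_for: list[str] = Field(
        default_factory=lambda: ["C_rugosus:intensity"],
        description="species:modality groups whose full model adds a squared centred contrast",
    )


class ObserverConfig(BaseModel):
    bottom: float = 0.05
    top: float = 0.95
    x50_pos: float = 0.2
    x50_neg: float = -0.2
    slope: float = 10.0
    crab_sd: float = 0.5
    habituation_decrement: float = 0.02


class SynthConfig(BaseModel):
    observer: ObserverConfig = ObserverConfig()
    n_crabs: int = 20
    contrast_set: list[float] = Field(
        default_factory=lambda: list(np.round(np.linspace(-0.5, 0.5, 9), 4))
    )
    modality: str = "polarization"
    species: str = "C_rugosus"


class RunConfig(BaseModel):
    """Validated pipeline configuration (YAML)."""

    seed: int = 0
    trials_csv: str | None = None
    synthdata: SynthConfig | None = None
    behaviour: BehaviourConfig = BehaviourConfig()
    polarimetry: PolarimetryConfig = PolarimetryConfig()
    out_dir: str = "polcrab_results"
    log_level: str = "INFO"
    make_figures: bool = True


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
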