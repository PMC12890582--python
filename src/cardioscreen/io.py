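"""File formats: WAV audio, cohort manifest CSV, predictions CSV, report JSON, config YAML."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .cohort import (
    AgeBand,
    EchoReport,
    Lesion,
    PatientRecord,
    Recording,
    Rhythm,
    Setting,
    SeverityGrade,
    Sex,
    Site,
)
from .preprocess import PreprocConfig
from .simulate import SimConfig

__all__ = [
    "write_wav", "read_wav", "write_manifest", "read_manifest",
    "write_predictions", "read_predictions", "write_report",
    "simconfig_to_dict", "simconfig_from_dict",
]


def write_wav(path: str | Path, samples: np.ndarray, fs: float) -> None:
    """16-bit PCM mono WAV."""
    x = np.clip(np.asarray(samples, dtype=np.float64), -1.0, 1.0)
    q = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(fs), q)


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    fs, q = wavfile.read(str(path))
    if q.dtype == np.int16:
        x = q.astype(np.float64) / 32767.0
    else:
        x = q.astype(np.float64)
    return x, float(fs)


_MANIFEST_COLUMNS = (
    ["id", "sex", "age_band", "setting", "rhythm"]
    + [s.value for s in Lesion]
    + ["significant"]
    + [f"murmur_{s.value}" for s in Site]
    + [f"files_{s.value}" for s in Site]
)


def write_manifest(cohort: list[PatientRecord], path: str | Path,
                   audio_dir: str | Path | None = None, fs: float | None = None) -> pd.DataFrame:
    """Write the cohort manifest CSV; optionally also write one WAV per recording
    (filenames ``<id>_<site>_<idx>.wav``) and record their relative paths."""
    rows = []
    audio_dir = Path(audio_dir) if audio_dir is not None else None
    if audio_dir is not None:
        audio_dir.mkdir(parents=True, exist_ok=True)
    for p in cohort:
        row: dict = {
            "id": p.id, "sex": p.sex.value, "age_band": p.age_band.value,
            "setting": p.setting.value, "rhythm": p.echo.rhythm.value,
        }
        for slot in Lesion:
            row[slot.value] = int(p.echo.grades[slot])
        row["significant"] = int(p.significant)
        for site in Site:
            row[f"murmur_{site.value}"] = int(bool(p.murmur_truth.get(site, False)))
        for site in Site:
            files = []
            for k, rec in enumerate(p.recordings.get(site, [])):
                if audio_dir is not None:
                    name = f"{p.id}_{site.value}_{k}.wav"
                    write_wav(audio_dir / name, rec.samples, rec.fs)
                    files.append(name)
                else:
                    files.append(f"{p.id}_{site.value}_{k}.wav")
            row[f"files_{site.value}"] = ";".join(files)
        rows.append(row)
    df = pd.DataFrame(rows, columns=_MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_manifest(path: str | Path, audio_dir: str | Path | None = None,
                  fs_default: float = 4000.0) -> list[PatientRecord]:
    """Read a manifest CSV back into patient records.

    Malformed rows raise a single error listing the offending line numbers.
    If ``audio_dir`` is given, WAVs are loaded; missing files produce a
    warning per patient and the recording is skipped.
    """
    import warnings

    df = pd.read_csv(path, keep_default_na=False)
    cohort: list[PatientRecord] = []
    bad: list[int] = []
    for i, row in df.iterrows():
        try:
            grades = {slot: SeverityGrade(int(row[slot.value])) for slot in Lesion}
            echo = EchoReport(grades=grades, rhythm=Rhythm(row["rhythm"]))
            recordings: dict[Site, list[Recording]] = {s: [] for s in Site}
            murmur = {s: bool(int(row.get(f"murmur_{s.value}", 0))) for s in Site}
            n_missing = 0
            for site in Site:
                cell = str(row.get(f"files_{site.value}", "") or "")
                for name in filter(None, cell.split(";")):
                    if audio_dir is None:
                        continue
                    f = Path(audio_dir) / name
                    if not f.exists():
                        n_missing += 1
                        continue
                    x, fs = read_wav(f)
                    recordings[site].append(Recording(site=site, samples=x, fs=fs))
            if n_missing:
                warnings.warn(f"patient {row['id']}: {n_missing} audio file(s) missing")
            cohort.append(PatientRecord(
                id=str(row["id"]), sex=Sex(row["sex"]), age_band=AgeBand(row["age_band"]),
                setting=Setting(row["setting"]), echo=echo,
                recordings=recordings, murmur_truth=murmur))
        except (KeyError, ValueError) as exc:  # noqa: PERF203
            bad.append(i + 2)  # 1-based line number incl. header
            last_err = exc
    if bad:
        raise ValueError(f"malformed manifest rows at lines {bad}: last error: {last_err}")
    return cohort


def write_predictions(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["id"] + [f"prob_{s.value}" for s in Site] + ["prob_fused"]
    if "label" in df.columns:
        cols.append("label")
    df.to_csv(path, index=False, columns=[c for c in cols if c in df.columns],
              float_format="%.10g")


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_report(report: dict, path: str | Path) -> None:
    """Deterministically serialised JSON report (sorted keys, fixed float repr)."""
    Path(path).write_text(json.dumps(_jsonable(report), sort_keys=True, indent=2) + "\n")


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, float) and np.isnan(x):
        return None
    return x


# ---------------------------------------------------------------------------
# config (de)serialisation

def simconfig_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["grade_frequencies"] = {k.value: list(map(float, v)) for k, v in cfg.grade_frequencies.items()}
    d["site_presence"] = {k.value: v for k, v in cfg.site_presence.items()}
    d["murmur_snr_by_grade"] = {int(k): v for k, v in cfg.murmur_snr_by_grade.items()}
    d["radiation_gains"] = {k.value: {s.value: g for s, g in v.items()}
                            for k, v in cfg.radiation_gains.items()}
    d["heart_rate_range"] = list(cfg.heart_rate_range)
    return d


def simconfig_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "grade_frequencies" in d:
        d["grade_frequencies"] = {Lesion(k): np.asarray(v, dtype=float)
                                  for k, v in d["grade_frequencies"].items()}
    if "site_presence" in d:
        d["site_presence"] = {Site(k): float(v) for k, v in d["site_presence"].items()}
    if "murmur_snr_by_grade" in d:
        d["murmur_snr_by_grade"] = {SeverityGrade(int(k)): float(v)
                                    for k, v in d["murmur_snr_by_grade"].items()}
    if "radiation_gains" in d:
        d["radiation_gains"] = {Lesion(k): {Site(s): float(g) for s, g in v.items()}
                                for k, v in d["radiation_gains"].items()}
    if "heart_rate_range" in d:
        d["heart_rate_range"] = tuple(d["heart_rate_range"])
    return SimConfig(**d)


def preprocconfig_to_dict(cfg: PreprocConfig) -> dict:
    return asdict(cfg)
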