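"""Record I/O: a minimal WFDB-subset (format 16) and delimited text.

WFDB records are a plain-text header (``<name>.hea``) plus a little-endian
16-bit sample file (``<name>.dat``, leads interleaved). Only the subset
needed for HRECG work is implemented: format 16, one .dat per record, gain
expressed in ADU/uV (gain 2 = the PTB database's 0.5 uV/LSB resolution).
Ground-truth metadata of synthetic records rides along in an optional
``<name>.meta.json`` sidecar so round trips preserve it.

CSV records are one column per lead with a ``# fs=<Hz>`` comment line;
values are written with full float precision so round trips are exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import RecordError
from .record import EcgRecord

WFDB_GAIN_DEFAULT = 2.0  # ADU per uV  <->  0.5 uV/LSB


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_record(
    record: EcgRecord,
    path: str | Path,
    format: str = "wfdb",
    gain: float = WFDB_GAIN_DEFAULT,
    with_meta: bool = True,
) -> None:
    """Write a record as a WFDB pair (``path``.hea/.dat) or a CSV file.

    WFDB samples are quantized to the nearest ADU (1/gain uV); CSV keeps
    full float precision.
    """
    path = Path(path)
    if format == "wfdb":
        _write_wfdb(record, path, gain)
    elif format == "csv":
        _write_csv(record, path)
    else:
        raise RecordError(f"unknown format '{format}'")
    if with_meta and record.meta:
        meta_path = path.with_suffix(path.suffix + ".meta.json") if format == "csv" else path.with_suffix(".meta.json")
        with open(meta_path, "w") as fh:
            json.dump(record.meta, fh, default=_json_default)


def read_record(path: str | Path, format: str | None = None, fs: float | None = None) -> EcgRecord:
    """Read a WFDB record (pass the header path or the record base name) or
    a CSV file; samples come back in uV."""
    path = Path(path)
    if format is None:
        if path.suffix in (".hea", ".dat") or path.with_suffix(".hea").exists():
            format = "wfdb"
        elif path.suffix == ".csv":
            format = "csv"
        else:
            raise RecordError(f"cannot infer format of '{path}'")
    if format == "wfdb":
        rec = _read_wfdb(path)
        meta_path = path.with_suffix(".meta.json")
    elif format == "csv":
        rec = _read_csv(path, fs=fs)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
    else:
        raise RecordError(f"unknown format '{format}'")
    if meta_path.exists():
        with open(meta_path) as fh:
            rec.meta.update(json.load(fh))
    return rec


# --------------------------------------------------------------------------
# WFDB subset

def _write_wfdb(record: EcgRecord, path: Path, gain: float) -> None:
    base = path.with_suffix("") if path.suffix in (".hea", ".dat") else path
    adu = np.round(record.signal * gain)
    if np.any(np.abs(adu) > 32767):
        raise RecordError("signal exceeds the int16 range at this gain")
    adu = adu.astype("<i2")
    checksums = (adu.astype(np.int64).sum(axis=0) % 65536).astype(int)
    fs_txt = f"{record.fs:g}"
    lines = [f"{base.name} {record.n_leads} {fs_txt} {record.n_samples}"]
    for j, name in enumerate(record.lead_names):
        lines.append(
            f"{base.name}.dat 16 {gain:g}(0)/uV 16 0 {int(adu[0, j])} {checksums[j]} 0 {name}"
        )
    base.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    adu.tofile(base.with_suffix(".dat"))


def _read_wfdb(path: Path) -> EcgRecord:
    base = path.with_suffix("") if path.suffix in (".hea", ".dat") else path
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise RecordError(f"missing header file '{hea}'")
    lines = [ln for ln in hea.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    try:
        n_sig, fs, n_samp = int(head[1]), float(head[2]), int(head[3])
    except (IndexError, ValueError) as e:
        raise RecordError(f"malformed header '{hea}': {e}") from e
    gains, baselines, names = [], [], []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        if tok[1] != "16":
            raise RecordError(f"unsupported WFDB format '{tok[1]}' (only 16)")
        gspec = tok[2]
        gpart = gspec.split("/")[0]
        if "(" in gpart:
            g, b = gpart.split("(")
            baselines.append(float(b.rstrip(")")))
        else:
            g = gpart
            baselines.append(0.0)
        gains.append(float(g))
        names.append(tok[-1] if len(tok) >= 9 else f"L{len(names)}")
    raw = np.fromfile(base.with_suffix(".dat"), dtype="<i2")
    if raw.size != n_sig * n_samp:
        raise RecordError("inconsistent .dat length vs header sample count")
    adu = raw.reshape(n_samp, n_sig).astype(float)
    signal = (adu - np.asarray(baselines)) / np.asarray(gains)
    return EcgRecord(signal=signal, fs=fs, lead_names=names)


# --------------------------------------------------------------------------
# CSV

def _write_csv(record: EcgRecord, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g}\n")
        pd.DataFrame(record.signal, columns=record.lead_names).to_csv(
            fh, index=False, float_format="%.17g"
        )


def _read_csv(path: Path, fs: float | None = None) -> EcgRecord:
    if not path.exists():
        raise RecordError(f"missing file '{path}'")
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# fs="):
            fs = float(first.split("=", 1)[1])
            df = pd.read_csv(fh, float_precision="round_trip")
        else:
            if fs is None:
                raise RecordError("CSV has no '# fs=' line; pass fs explicitly")
            fh.seek(0)
            df = pd.read_csv(fh, float_precision="round_trip")
    return EcgRecord(signal=df.to_numpy(dtype=float), fs=fs, lead_names=list(df.columns))
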