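"""Reading/writing cytometry samples and intensity preprocessing.

Samples are read either from CSV (one header row of marker names, one cell
per row) or from FCS 3.0/3.1 list-mode files.  The FCS reader/writer here is
a deliberately small one covering the list-mode float/double layout that
cytometer export software produces; channel (``$PnN``) names are mapped to
panel marker names through a user-supplied two-column channel map.

Preprocessing follows the usual cytometry convention: a per-marker arcsinh
transform with a configurable cofactor, then per-marker standardisation with
optional regression of nuisance covariates (batch/institute) out of the
pooled cohort before clustering.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CellMatrix, Cohort

log = logging.getLogger(__name__)

DEFAULT_COFACTOR = 150.0


# ---------------------------------------------------------------------------
# CSV + FCS round trips
# ---------------------------------------------------------------------------

def write_sample(m: CellMatrix, path: str | Path, format: str = "csv") -> None:
    """Write one sample; CSV keeps full float precision (repr round-trip)."""
    path = Path(path)
    if format == "csv":
        m.to_frame().to_csv(path, index=False, float_format="%.17g")
    elif format == "fcs":
        _write_fcs(path, m.values, m.markers)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_sample(path: str | Path, format: str = "csv", *,
                sample_id: str | None = None, subject_id: str | None = None,
                batch: str = "batch0",
                channel_map: dict[str, str] | None = None,
                markers: list[str] | None = None) -> CellMatrix:
    """Read a raw-scale sample from ``path``.

    Parameters
    ----------
    format : {"csv", "fcs"}
    channel_map : dict, optional
        FCS channel name -> panel marker name. Required whenever FCS channel
        names differ from panel marker names.
    markers : list of str, optional
        If given, the panel the sample must provide (after channel mapping);
        unknown or missing names are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sid = sample_id or path.stem
    if format == "csv":
        df = pd.read_csv(path)
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError(f"empty sample file: {path}")
        names = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    elif format == "fcs":
        values, names = _read_fcs(path)
        if values.shape[0] == 0:
            raise ValueError(f"empty sample file: {path}")
    else:
        raise ValueError(f"unknown format {format!r}")

    if channel_map is not None:
        unmapped = [n for n in names if n not in channel_map]
        if unmapped:
            raise KeyError(f"channels with no map entry: {unmapped}")
        names = [channel_map[n] for n in names]
    if markers is not None:
        missing = [mk for mk in markers if mk not in names]
        if missing:
            raise KeyError(f"sample {path.name} is missing channels for "
                           f"markers: {missing}")
        order = [names.index(mk) for mk in markers]
        values = values[:, order]
        names = list(markers)
    return CellMatrix(values=values, markers=names, sample_id=sid,
                      subject_id=subject_id or sid, batch=batch,
                      transformed=False)


def read_channel_map(path: str | Path) -> dict[str, str]:
    """Two-column CSV ``channel,marker`` -> dict."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("channel map needs two columns: channel, marker")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


# -- minimal FCS 3.0/3.1 list-mode support ----------------------------------

_DELIM = b"/"


def _write_fcs(path: Path, values: np.ndarray, markers: list[str]) -> None:
    values = np.asarray(values, dtype="<f4")
    n_cells, n_par = values.shape
    kw = {
        "$DATATYPE": "F", "$MODE": "L", "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par), "$TOT": str(n_cells), "$NEXTDATA": "0",
    }
    for j, name in enumerate(markers, start=1):
        kw[f"$P{j}N"] = name
        kw[f"$P{j}B"] = "32"
        kw[f"$P{j}E"] = "0,0"
        kw[f"$P{j}R"] = "262144"

    def render(extra: dict[str, str]) -> bytes:
        parts = [_DELIM]
        for k, v in {**kw, **extra}.items():
            parts += [k.encode(), _DELIM, str(v).encode(), _DELIM]
        return b"".join(parts)

    # two passes: the BEGIN/ENDDATA keywords change their own width
    text = render({"$BEGINDATA": "0", "$ENDDATA": "0"})
    for _ in range(3):
        text_start = 58
        data_start = text_start + len(text)
        data_end = data_start + values.nbytes - 1
        new = render({"$BEGINDATA": str(data_start), "$ENDDATA": str(data_end)})
        if len(new) == len(text):
            text = new
            break
        text = new
    header = (b"FCS3.1    "
              + f"{text_start:8d}".encode()
              + f"{text_start + len(text) - 1:8d}".encode()
              + f"{0:8d}".encode() + f"{0:8d}".encode()
              + f"{0:8d}".encode() + f"{0:8d}".encode())
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(values.tobytes())


def _read_fcs(path: Path) -> tuple[np.ndarray, list[str]]:
    raw = Path(path).read_bytes()
    if len(raw) < 58 or not raw[:3] == b"FCS":
        raise ValueError(f"not an FCS file: {path}")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_start:text_end + 1]
    delim = text[:1]
    fields = text[1:].split(delim)
    kw = {fields[i].decode("utf-8", "replace").strip():
          fields[i + 1].decode("utf-8", "replace")
          for i in range(0, len(fields) - 1, 2)}
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    dtype_code = kw.get("$DATATYPE", "F").upper()
    if dtype_code not in ("F", "D"):
        raise ValueError(f"unsupported FCS $DATATYPE {dtype_code!r} "
                         "(only float list mode supported)")
    if kw.get("$MODE", "L").upper() != "L":
        raise ValueError("only list-mode FCS supported")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    item = "f4" if dtype_code == "F" else "f8"
    data_start = int(raw[26:34]) or int(kw["$BEGINDATA"])
    data_end = int(raw[34:42]) or int(kw["$ENDDATA"])
    buf = raw[data_start:data_end + 1]
    values = np.frombuffer(buf, dtype=endian + item,
                           count=n_par * n_tot).reshape(n_tot, n_par)
    names = [kw.get(f"$P{j}N", f"P{j}") for j in range(1, n_par + 1)]
    return values.astype(float), names


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def arcsinh_transform(m: CellMatrix, cofactor: float = DEFAULT_COFACTOR
                      ) -> CellMatrix:
    """Elementwise ``asinh(x / cofactor)``; refuses to transform twice."""
    if m.transformed:
        raise ValueError(f"sample {m.sample_id} is already transformed "
                         "(double arcsinh forbidden)")
    if not np.isfinite(cofactor) or cofactor <= 0:
        raise ValueError("cofactor must be a positive real")
    return m.copy_with(values=np.arcsinh(m.values / cofactor), transformed=True)


def transform_cohort(cohort: Cohort, cofactor: float = DEFAULT_COFACTOR
                     ) -> Cohort:
    return Cohort(samples=[arcsinh_transform(s, cofactor) for s in cohort.samples],
                  subjects=cohort.subjects.copy(), cell_truth=cohort.cell_truth)


def scale_and_regress(cohort: Cohort, covariates: list[str] | None = None
                      ) -> Cohort:
    """Regress out metadata covariates and standardise each marker.

    Per marker, a linear model of expression on the covariate indicator
    columns is fitted across *all pooled cells* of the cohort; values are
    replaced by the residuals, then centred to mean 0 and scaled to unit
    variance.  With no covariates this is plain per-marker standardisation.
    Zero-variance markers are set to all zeros (with a logged warning)
    rather than producing NaNs.
    """
    covariates = list(covariates or [])
    if not cohort.transformed_all():
        raise ValueError("all samples must be arcsinh-transformed before "
                         "scale_and_regress")
    X, meta = cohort.pooled()
    n = X.shape[0]

    design = [np.ones((n, 1))]
    for cov in covariates:
        if cov not in meta.columns:
            raise KeyError(f"covariate {cov!r} not in cohort metadata")
        levels = pd.unique(meta[cov])
        if len(levels) < 2:
            raise ValueError(f"covariate {cov!r} has a single level "
                             f"({levels[0]!r}); no contrast to fit")
        # one-hot minus reference level
        for lev in levels[1:]:
            design.append((meta[cov].to_numpy() == lev)[:, None].astype(float))
    D = np.hstack(design)

    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    resid = X - D @ beta
    mean = resid.mean(axis=0)
    sd = resid.std(axis=0, ddof=0)
    degenerate = sd < 1e-12
    if degenerate.any():
        bad = [cohort.markers[j] for j in np.flatnonzero(degenerate)]
        log.warning("zero-variance markers set to 0 after centering: %s", bad)
        warnings.warn(f"zero-variance markers set to 0: {bad}", stacklevel=2)
    scaled = (resid - mean) / np.where(degenerate, 1.0, sd)
    scaled[:, degenerate] = 0.0

    out_samples = []
    start = 0
    for s in cohort.samples:
        stop = start + s.n_cells
        out_samples.append(s.copy_with(values=scaled[start:stop]))
        start = stop
    return Cohort(samples=out_samples, subjects=cohort.subjects.copy(),
                  cell_truth=cohort.cell_truth)


# ---------------------------------------------------------------------------
# Cohort-level disk layout
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, directory: str | Path,
                 format: str = "csv") -> None:
    """One sample file per subject plus a ``subjects.csv`` metadata table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s in cohort.samples:
        write_sample(s, directory / f"{s.sample_id}.{format}", format=format)
    meta = cohort.subjects.copy()
    meta["sample_file"] = [f"{s.sample_id}.{format}" for s in cohort.samples]
    meta["transformed"] = [s.transformed for s in cohort.samples]
    meta.to_csv(directory / "subjects.csv", index=False)


def read_cohort(directory: str | Path, format: str = "csv") -> Cohort:
    directory = Path(directory)
    meta = pd.read_csv(directory / "subjects.csv")
    meta = meta.where(pd.notna(meta), None)
    samples = []
    for _, row in meta.iterrows():
        m = read_sample(directory / row["sample_file"], format=format,
                        sample_id=str(row["subject_id"]),
                        subject_id=str(row["subject_id"]),
                        batch=str(row["batch"]))
        if bool(row.get("transformed", False)):
            m = m.copy_with(transformed=True)
        samples.append(m)
    cols = [c for c in meta.columns if c not in ("sample_file", "transformed")]
    return Cohort(samples=samples, subjects=meta[cols])
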