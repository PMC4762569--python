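"""Readers and writers for the classic small-angle-scattering text formats.

Four ASCII formats circulate in the SAS community and are bridged here:

``.dat``
    the experimental curve — momentum transfer *s*, intensity I(s) and its
    error, three whitespace-separated columns, optionally preceded by
    name–value metadata lines;
``.out``
    indirect-transform output — the pair-distance distribution p(r) as a
    three-column table, the regularized reciprocal-space fit as a
    five-column table (with a leading two-column extrapolation to s = 0),
    and the derived parameters Rg, I(0) and Dmax;
``.fit`` / ``.fir``
    model-versus-data fits, three and four columns respectively (the
    ``.fir`` dialect carries experimental errors), with the reduced χ²
    and/or correlation-map p value in the header;
``.pdb``
    fixed-column coordinate records (ATOM/HETATM) for atomic, rigid-body
    or ab initio bead models.

The writers use a canonical layout (``%.6e`` table numbers, ``%8.3f`` PDB
coordinates); the readers are tolerant, keying on labels and column counts
rather than byte positions, so files from other software parse as long as
the tables themselves are well formed.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "FormatError",
    "ScatteringCurve",
    "DistanceDistribution",
    "ModelFit",
    "Atom",
    "AtomicModel",
    "read_dat",
    "write_dat",
    "read_out",
    "write_out",
    "read_fitfile",
    "write_fitfile",
    "read_pdb",
    "write_pdb",
]

_NUM = "%14.6e"


class FormatError(ValueError):
    """Input text does not follow the expected legacy format."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def _check_increasing(arr: np.ndarray, name: str) -> None:
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise FormatError(f"{name} values must be strictly increasing")


@dataclass
class ScatteringCurve:
    """One-dimensional scattering profile I(s) with optional errors.

    ``unit`` records the momentum-transfer unit (``1/angstrom`` or
    ``1/nm``); ``metadata`` keeps the header name–value pairs in file
    order.
    """

    s: np.ndarray
    I: np.ndarray
    err: np.ndarray | None = None
    metadata: dict[str, str] = field(default_factory=dict)
    unit: str | None = None

    def __post_init__(self):
        self.s = _as_float_array(self.s, "s")
        self.I = _as_float_array(self.I, "I")
        if self.err is not None:
            self.err = _as_float_array(self.err, "err")
            if len(self.err) != len(self.s):
                raise ValueError("err length differs from s")
        if len(self.I) != len(self.s):
            raise ValueError("I length differs from s")
        if np.any(self.s < 0):
            raise ValueError("momentum transfer must be non-negative")
        _check_increasing(self.s, "s")

    def __len__(self) -> int:
        return len(self.s)


@dataclass
class DistanceDistribution:
    """Pair-distance distribution p(r) plus its reciprocal-space fit.

    The fit table holds, per momentum-transfer value: experimental
    intensity and error (NaN on the extrapolated rows below the lowest
    measured s), the regularized fit I_reg and the extrapolation I_ext,
    which is defined on every row down to s = 0.
    """

    r: np.ndarray
    p: np.ndarray
    perr: np.ndarray | None
    fit_s: np.ndarray
    fit_iexp: np.ndarray
    fit_err: np.ndarray
    fit_ireg: np.ndarray
    fit_iext: np.ndarray
    Rg: float
    I0: float
    Dmax: float
    software: str | None = None

    def __post_init__(self):
        self.r = _as_float_array(self.r, "r")
        self.p = _as_float_array(self.p, "p")
        if self.perr is not None:
            self.perr = _as_float_array(self.perr, "perr")
        for name in ("fit_s", "fit_iexp", "fit_err", "fit_ireg", "fit_iext"):
            setattr(self, name, _as_float_array(getattr(self, name), name))
        if len(self.p) != len(self.r):
            raise ValueError("p length differs from r")
        if abs(self.r[0]) > 1e-12:
            raise ValueError("r grid must start at 0")
        _check_increasing(self.r, "r")
        _check_increasing(self.fit_s, "fit s")
        lengths = {len(self.fit_s), len(self.fit_iexp), len(self.fit_err),
                   len(self.fit_ireg), len(self.fit_iext)}
        if len(lengths) != 1:
            raise ValueError("fit table columns have unequal lengths")

    @property
    def experimental(self) -> np.ndarray:
        """Boolean mask of fit rows backed by measured data."""
        return ~np.isnan(self.fit_iexp)


@dataclass
class ModelFit:
    """Computed model scattering against an experimental curve."""

    s: np.ndarray
    Iexp: np.ndarray
    Ifit: np.ndarray
    err: np.ndarray | None = None
    chi2_reduced: float | None = None
    cormap_p: float | None = None
    model_id: int | None = None

    def __post_init__(self):
        self.s = _as_float_array(self.s, "s")
        self.Iexp = _as_float_array(self.Iexp, "Iexp")
        self.Ifit = _as_float_array(self.Ifit, "Ifit")
        if self.err is not None:
            self.err = _as_float_array(self.err, "err")
            if len(self.err) != len(self.s):
                raise ValueError("err length differs from s")
        if not (len(self.Iexp) == len(self.Ifit) == len(self.s)):
            raise ValueError("fit columns have unequal lengths")
        _check_increasing(self.s, "s")

    def __len__(self) -> int:
        return len(self.s)


@dataclass
class Atom:
    record: str  # ATOM or HETATM
    serial: int
    name: str
    res_name: str
    chain_id: str
    res_seq: int
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    b_factor: float = 0.0
    element: str = ""


@dataclass
class AtomicModel:
    """Ordered coordinate records plus SAS model metadata.

    ``model_type`` is one of ``ab initio`` (dummy-bead shape), ``rigid
    body`` or ``atomic``; ``bead_radius`` (Å) applies to bead models only.
    """

    atoms: list[Atom]
    model_type: str = "atomic"
    symmetry: str | None = None
    bead_radius: float | None = None
    software: str | None = None

    def __post_init__(self):
        for a in self.atoms:
            if a.serial <= 0:
                raise ValueError(f"atom serial {a.serial} must be positive")
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValueError(f"atom {a.serial} has non-finite coordinates")

    def coordinates(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)


# ---------------------------------------------------------------------------
# .dat

def _try_floats(line: str) -> list[float] | None:
    parts = line.split()
    if not parts:
        return None
    try:
        return [float(p) for p in parts]
    except ValueError:
        return None


def read_dat(text: str) -> ScatteringCurve:
    """Parse a two- or three-column ``.dat`` scattering curve.

    Leading non-numeric lines become metadata (split at the first ``:`` or
    ``=``); lines after the numeric block are ignored with a warning.
    """
    metadata: dict[str, str] = {}
    rows: list[list[float]] = []
    trailing = False
    for line in text.splitlines():
        if not line.strip():
            continue
        vals = _try_floats(line)
        if vals is not None and len(vals) >= 2:
            if trailing:
                warnings.warn("numeric data after trailing text ignored")
                continue
            rows.append(vals[:3])
        elif not rows:
            m = re.match(r"\s*#?\s*([^:=]+?)\s*[:=]\s*(.*?)\s*$", line)
            if m:
                metadata[m.group(1)] = m.group(2)
            else:
                metadata[line.strip().lstrip("#").strip()] = ""
        else:
            trailing = True
            warnings.warn(f"trailing non-numeric text ignored: {line.strip()!r}")
    if not rows:
        raise FormatError("no numeric data rows with at least two columns")
    ncol = min(len(r) for r in rows)
    if ncol < 2:
        raise FormatError("fewer than two parsable numeric columns")
    arr = np.array([r[:ncol] for r in rows], dtype=float)
    err = arr[:, 2] if ncol >= 3 else None
    unit = metadata.get("Unit") or metadata.get("unit")
    return ScatteringCurve(arr[:, 0], arr[:, 1], err, metadata, unit)


def write_dat(curve: ScatteringCurve, three_columns: bool = True) -> str:
    """Write a curve in the three-column ``.dat`` layout.

    When errors are absent the third column is written as zeros to keep
    the three-column contract; pass ``three_columns=False`` for genuine
    two-column output.
    """
    lines = [f"{k} : {v}" for k, v in curve.metadata.items()]
    err = curve.err
    if err is None and three_columns:
        err = np.zeros_like(curve.s)
    for i in range(len(curve)):
        if err is None:
            lines.append(f"{_NUM % curve.s[i]} {_NUM % curve.I[i]}")
        else:
            lines.append(
                f"{_NUM % curve.s[i]} {_NUM % curve.I[i]} {_NUM % err[i]}"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# .out

_LABEL_RES = {
    "Dmax": re.compile(r"d\s*max[^0-9+\-]*([+\-]?\d[\d.]*(?:[eE][+\-]?\d+)?)", re.I),
    "Rg": re.compile(r"\brg\b[^0-9+\-]*([+\-]?\d[\d.]*(?:[eE][+\-]?\d+)?)", re.I),
    "I0": re.compile(r"i\s*\(\s*0\s*\)[^0-9+\-]*([+\-]?\d[\d.]*(?:[eE][+\-]?\d+)?)", re.I),
}


def read_out(text: str) -> DistanceDistribution:
    """Parse an indirect-transform ``.out`` file.

    The reciprocal-fit section is the contiguous run of five-column rows
    (with adjacent leading two-column extrapolation rows); the real-space
    section is the following run of three-column rows.  Rg, I(0) and Dmax
    are located by label search in the non-numeric lines.
    """
    params: dict[str, float] = {}
    software = None
    lines = text.splitlines()
    numeric: list[tuple[int, list[float]]] = []  # (line index, values)
    for idx, line in enumerate(lines):
        vals = _try_floats(line)
        if vals is not None:
            numeric.append((idx, vals))
        else:
            for key, rex in _LABEL_RES.items():
                if key not in params:
                    m = rex.search(line)
                    if m:
                        params[key] = float(m.group(1))
            m = re.match(r"\s*#?\s*software\s*[:=]\s*(\S.*?)\s*$", line, re.I)
            if m:
                software = m.group(1)

    # segment numeric rows into contiguous runs (broken by non-numeric lines)
    runs: list[list[list[float]]] = []
    prev_idx = None
    for idx, vals in numeric:
        if prev_idx is None or idx != prev_idx + 1:
            runs.append([])
        runs[-1].append(vals)
        prev_idx = idx

    recip_run = None
    preal = None
    for run in runs:
        counts = {len(v) for v in run}
        if 5 in counts and counts <= {2, 5} and recip_run is None:
            recip_run = run
        elif counts == {3} and recip_run is not None and preal is None:
            preal = run
    if recip_run is None:
        raise FormatError("reciprocal-space fit section (five columns) not found")
    if preal is None:
        raise FormatError("real-space p(r) section (three columns) not found")

    n = len(recip_run)
    fit_s = np.empty(n)
    fit = np.full((n, 4), np.nan)  # iexp, err, ireg, iext
    for i, vals in enumerate(recip_run):
        fit_s[i] = vals[0]
        if len(vals) == 5:
            fit[i, :] = vals[1:5]
        else:  # extrapolated row: s and I_ext only
            fit[i, 3] = vals[1]
    pr = np.array(preal, dtype=float)

    missing = [k for k in ("Dmax", "Rg", "I0") if k not in params]
    if missing:
        raise FormatError(f"labeled parameters not found: {', '.join(missing)}")
    return DistanceDistribution(
        r=pr[:, 0], p=pr[:, 1], perr=pr[:, 2],
        fit_s=fit_s, fit_iexp=fit[:, 0], fit_err=fit[:, 1],
        fit_ireg=fit[:, 2], fit_iext=fit[:, 3],
        Rg=params["Rg"], I0=params["I0"], Dmax=params["Dmax"],
        software=software,
    )


def write_out(dist: DistanceDistribution) -> str:
    """Write the canonical ``.out`` layout (labeled header + two tables)."""
    lines = [
        "    ####    Distance distribution function    ####",
        "",
    ]
    if dist.software:
        lines.append(f" Software : {dist.software}")
    lines += [
        f" Dmax : {_NUM % dist.Dmax}",
        f" Rg   : {_NUM % dist.Rg}",
        f" I(0) : {_NUM % dist.I0}",
        "",
        "    ####    Experimental and regularized fit    ####",
        "",
        "      s          I_exp         error         I_reg         I_ext",
    ]
    for i in range(len(dist.fit_s)):
        if np.isnan(dist.fit_iexp[i]):
            lines.append(f"{_NUM % dist.fit_s[i]} {_NUM % dist.fit_iext[i]}")
        else:
            lines.append(
                " ".join(
                    _NUM % v
                    for v in (
                        dist.fit_s[i], dist.fit_iexp[i], dist.fit_err[i],
                        dist.fit_ireg[i], dist.fit_iext[i],
                    )
                )
            )
    lines += [
        "",
        "    ####    Real space distance distribution    ####",
        "",
        "      r          p(r)          error",
    ]
    perr = dist.perr if dist.perr is not None else np.zeros_like(dist.r)
    for i in range(len(dist.r)):
        lines.append(f"{_NUM % dist.r[i]} {_NUM % dist.p[i]} {_NUM % perr[i]}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# .fit / .fir

_CHI2_RE = re.compile(
    r"(?:chi\^?2|chi-square)\s*[:=]?\s*([+\-]?\d+\.?\d*(?:[eE][+\-]?\d+)?)", re.I
)
_PVAL_RE = re.compile(
    r"(?:cormap\s*)?p[\s-]?value\s*[:=]?\s*([+\-]?\d+\.?\d*(?:[eE][+\-]?\d+)?)", re.I
)


def read_fitfile(text: str, dialect: str | None = None) -> ModelFit:
    """Parse a model-fit file.

    ``dialect`` is ``"fit"`` (three columns: s, I_exp, I_fit) or ``"fir"``
    (four columns: s, I_exp, error, I_fit); when omitted it is inferred
    from the column count.  The header is scanned for a reduced χ² token
    and a correlation-map p value.
    """
    if dialect not in (None, "fit", "fir"):
        raise ValueError(f"unknown fit dialect {dialect!r}")
    chi2 = None
    pval = None
    rows: list[list[float]] = []
    for line in text.splitlines():
        if not line.strip():
            continue
        vals = _try_floats(line)
        if vals is not None and len(vals) >= 3:
            rows.append(vals)
        elif not rows:
            m = _CHI2_RE.search(line)
            if m:
                chi2 = float(m.group(1))
            m = _PVAL_RE.search(line)
            if m:
                pval = float(m.group(1))
    if not rows:
        raise FormatError("no numeric fit rows found")
    counts = {len(r) for r in rows}
    if len(counts) != 1:
        raise FormatError(f"inconsistent column counts {sorted(counts)}")
    ncol = counts.pop()
    expected = {None: ncol, "fit": 3, "fir": 4}[dialect]
    if ncol != expected or ncol not in (3, 4):
        raise FormatError(
            f"{ncol}-column table inconsistent with "
            f"{dialect or 'fit/fir'} dialect"
        )
    arr = np.array(rows, dtype=float)
    if ncol == 4:
        return ModelFit(arr[:, 0], arr[:, 1], arr[:, 3], err=arr[:, 2],
                        chi2_reduced=chi2, cormap_p=pval)
    return ModelFit(arr[:, 0], arr[:, 1], arr[:, 2],
                    chi2_reduced=chi2, cormap_p=pval)


def write_fitfile(fit: ModelFit, dialect: str = "fit") -> str:
    """Write a fit as ``.fit`` (3 columns) or ``.fir`` (4 columns).

    χ² and p-value header tokens are emitted only when set on the fit.
    """
    if dialect not in ("fit", "fir"):
        raise ValueError(f"unknown fit dialect {dialect!r}")
    if dialect == "fir" and fit.err is None:
        raise ValueError("fir dialect requires experimental errors")
    header_bits = []
    if fit.chi2_reduced is not None:
        header_bits.append(f"Chi^2: {fit.chi2_reduced:.6g}")
    if fit.cormap_p is not None:
        header_bits.append(f"p-value: {fit.cormap_p:.6g}")
    lines = []
    if header_bits:
        lines.append("# " + "   ".join(header_bits))
    for i in range(len(fit)):
        if dialect == "fir":
            cols = (fit.s[i], fit.Iexp[i], fit.err[i], fit.Ifit[i])
        else:
            cols = (fit.s[i], fit.Iexp[i], fit.Ifit[i])
        lines.append(" ".join(_NUM % v for v in cols))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PDB

def read_pdb(text: str) -> AtomicModel:
    """Read ATOM/HETATM records from fixed-column PDB text.

    Only the first model of a multi-model file is read; all other record
    types are ignored.  An unparsable coordinate or serial field raises
    :class:`FormatError` with the line number.
    """
    atoms: list[Atom] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip().upper()
        if record == "ENDMDL" and atoms:
            break
        if record not in ("ATOM", "HETATM"):
            continue
        try:
            serial = int(line[6:11])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise FormatError(
                f"line {lineno}: unparsable numeric field in {record} record "
                f"({exc})"
            ) from None
        def _float(fld: str, default: float) -> float:
            fld = fld.strip()
            return float(fld) if fld else default
        try:
            occ = _float(line[54:60], 1.0)
            bfac = _float(line[60:66], 0.0)
        except ValueError:
            raise FormatError(
                f"line {lineno}: unparsable occupancy/B-factor field"
            ) from None
        res_seq_s = line[22:26].strip()
        try:
            res_seq = int(res_seq_s) if res_seq_s else 0
        except ValueError:
            raise FormatError(f"line {lineno}: unparsable residue number") from None
        atoms.append(Atom(
            record=record,
            serial=serial,
            name=line[12:16].strip(),
            res_name=line[17:20].strip(),
            chain_id=line[21:22].strip() or "A",
            res_seq=res_seq,
            x=x, y=y, z=z,
            occupancy=occ,
            b_factor=bfac,
            element=line[76:78].strip(),
        ))
    return AtomicModel(atoms=atoms)


def _pdb_atom_name(name: str) -> str:
    # one/two-letter element names start in column 14 by PDB convention
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3}"


def write_pdb(model: AtomicModel) -> str:
    """Write fixed-column PDB text (coordinates as %8.3f)."""
    lines = []
    if model.model_type:
        lines.append(f"REMARK   model type: {model.model_type}")
    if model.software:
        lines.append(f"REMARK   software: {model.software}")
    if model.bead_radius is not None:
        lines.append(f"REMARK   bead radius: {model.bead_radius:.3f}")
    for a in model.atoms:
        lines.append(
            f"{a.record:<6}{a.serial:>5} {_pdb_atom_name(a.name)} "
            f"{a.res_name:>3} {a.chain_id:1}{a.res_seq:>4}    "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
            f"          {a.element:>2}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
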