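"""Converters between sasCIF files and the legacy SAS formats.

Each ``*2cif`` function inserts one kind of data into a :class:`CifFile`
(curve, distance distribution, model, fit), touching only its target
block; each ``cif2*`` function extracts it back.  :func:`collect` builds a
complete entry from a file set in one call and :func:`cif2all` explodes an
entry back into the individual files.

Insertion honours a conflict policy: by default a converter refuses to
overwrite a category that is already present (``policy="error"``);
``policy="replace"`` makes re-running an insert idempotent.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

from .cif import Category, CifFile, DataBlock, parse_cif, write_cif
from .formats import (
    AtomicModel,
    DistanceDistribution,
    ModelFit,
    ScatteringCurve,
    read_dat,
    read_fitfile,
    read_out,
    read_pdb,
    write_dat,
    write_fitfile,
    write_out,
    write_pdb,
)
from .model import (
    EntryError,
    FIT_BLOCK_RE,
    MAIN_BLOCK_RE,
    MODEL_BLOCK_RE,
    Registry,
    block_label,
    decode_curve,
    decode_fit,
    decode_model,
    encode_curve,
    encode_distribution,
    encode_fit,
    encode_model,
    load_registry,
    _decode_distribution,
    _merge_scalar,
    _scalar_float,
    _scalar_int,
    _scalar_text,
)

__all__ = [
    "ConflictError",
    "ConversionContext",
    "dat2cif",
    "cif2dat",
    "out2cif",
    "cif2out",
    "rebin_to_grid",
    "pdb2cif",
    "cif2pdb",
    "fit2cif",
    "cif2fit",
    "cif2sub",
    "cif2all",
    "collect",
    "read_flat_config",
    "write_flat_config",
    "ManifestEntry",
]

log = logging.getLogger("sascifio")

_BLOCK_RES = (MAIN_BLOCK_RE, MODEL_BLOCK_RE, FIT_BLOCK_RE)


class ConflictError(ValueError):
    """Target category already present and the policy forbids overwriting."""


@dataclass
class ConversionContext:
    """Shared knobs for the insert converters.

    ``block``: target block label (defaults to the scheme-appropriate one);
    ``overwrite``: ``"error"`` or ``"replace"``;
    ``unit``: declared momentum-transfer unit for inserted curves/fits.
    """

    block: str | None = None
    overwrite: str = "error"
    unit: str = "1/angstrom"
    logger: logging.Logger = field(default_factory=lambda: log)

    def __post_init__(self):
        if self.overwrite not in ("error", "replace"):
            raise ValueError("overwrite policy must be 'error' or 'replace'")
        if self.block is not None and not any(
            rex.match(self.block) for rex in _BLOCK_RES
        ):
            raise ValueError(
                f"block label {self.block!r} does not follow the "
                "MAIN/MODEL/FIT naming scheme"
            )


def _ctx(ctx: ConversionContext | None) -> ConversionContext:
    return ctx if ctx is not None else ConversionContext()


def _conflict(block: DataBlock, category: str, ctx: ConversionContext) -> None:
    if block.get(category) is None:
        return
    if ctx.overwrite == "error":
        raise ConflictError(
            f"block {block.name} already holds {category}; "
            "pass overwrite='replace' to replace it"
        )
    ctx.logger.info("replacing %s in block %s", category, block.name)


def _main_blocks(file: CifFile) -> list[DataBlock]:
    return [b for b in file.blocks if MAIN_BLOCK_RE.match(b.name)]


def _model_blocks(file: CifFile) -> list[DataBlock]:
    return [b for b in file.blocks if MODEL_BLOCK_RE.match(b.name)]


def _fit_blocks(file: CifFile) -> list[DataBlock]:
    return [b for b in file.blocks if FIT_BLOCK_RE.match(b.name)]


def _next_label(file: CifFile, kind: str) -> str:
    i = 1
    existing = {b.name.lower() for b in file.blocks}
    while block_label(kind, i).lower() in existing:
        i += 1
    return block_label(kind, i)


# ---------------------------------------------------------------------------
# curves

def dat2cif(curve: ScatteringCurve, file: CifFile,
            ctx: ConversionContext | None = None) -> CifFile:
    """Insert an experimental curve into the MAIN block.

    The intensity table goes to ``sas_scan_intensity``; recognised header
    metadata routes to ``sas_scan`` (temperatures, frame count, unit) and
    ``sas_sample`` (name, concentration); the momentum-transfer range
    items are set from the grid extremes.
    """
    ctx = _ctx(ctx)
    block = file.ensure_block(ctx.block or "MAIN")
    _conflict(block, "sas_scan_intensity", ctx)
    block.remove("sas_scan_intensity")
    block.remove("sas_scan_metadata")
    if curve.unit is None:
        curve = ScatteringCurve(curve.s, curve.I, curve.err,
                                dict(curve.metadata), ctx.unit)
    encode_curve(block, curve)
    return file


def cif2dat(file: CifFile) -> list[ScatteringCurve]:
    """Extract every stored curve, one per MAIN-family block."""
    curves = []
    for block in _main_blocks(file):
        curve = decode_curve(block)
        if curve is not None:
            curves.append(curve)
    if not curves:
        warnings.warn("no sas_scan_intensity loop found in any MAIN block")
    return curves


# ---------------------------------------------------------------------------
# distance distributions

def rebin_to_grid(src_s, src_I, dst_s) -> np.ndarray:
    """Linearly interpolate intensities onto a destination grid.

    Destination points outside the source range come back as NaN
    (absent).  Both grids must be strictly increasing.
    """
    src_s = np.asarray(src_s, dtype=float)
    src_I = np.asarray(src_I, dtype=float)
    dst_s = np.asarray(dst_s, dtype=float)
    if src_s.size < 2:
        raise ValueError("need at least two source points to re-bin")
    for name, arr in (("source", src_s), ("destination", dst_s)):
        if arr.size > 1 and not np.all(np.diff(arr) > 0):
            raise ValueError(f"{name} grid must be strictly increasing")
    out = np.interp(dst_s, src_s, src_I)
    out[(dst_s < src_s[0]) | (dst_s > src_s[-1])] = np.nan
    return out


def out2cif(dist: DistanceDistribution, file: CifFile,
            ctx: ConversionContext | None = None) -> CifFile:
    """Insert a distance distribution into the MAIN block.

    Writes the three categories: the p(r) loop, the regularized/
    extrapolated intensity loop, and the detail scalars (Dmax, Rg, I(0),
    software).
    """
    ctx = _ctx(ctx)
    block = file.ensure_block(ctx.block or "MAIN")
    _conflict(block, "sas_p_of_r", ctx)
    encode_distribution(block, dist)
    return file


def cif2out(file: CifFile) -> DistanceDistribution:
    """Reconstruct the distance distribution and its reciprocal fit.

    The stored regularized intensities are translated back onto the same
    Δs bins as the experimental curve (linear re-binning onto the
    ``sas_scan_intensity`` grid); the extrapolated part below the lowest
    experimental momentum transfer stays on its stored grid, reaching
    s = 0.
    """
    target = None
    for block in _main_blocks(file):
        if block.get("sas_p_of_r") is not None:
            target = block
            break
    if target is None:
        raise EntryError("no sas_p_of_R category found in any MAIN block")
    curve = decode_curve(target)
    stored = _decode_distribution(target, curve)
    assert stored is not None
    if curve is None or len(curve) < 2:
        return stored
    s_min = float(curve.s[0])
    fs = stored.fit_s
    meas = fs >= s_min * (1 - 1e-9)
    extrap_s = fs[~meas]
    extrap_i = stored.fit_iext[~meas]
    if meas.sum() >= 2:
        reg = rebin_to_grid(fs[meas], stored.fit_iext[meas], curve.s)
        keep = ~np.isnan(reg)
    else:  # nothing measurable stored; keep stored grid as-is
        return stored
    exp_s = curve.s[keep]
    exp_reg = reg[keep]
    idx = np.flatnonzero(keep)
    iexp = curve.I[idx]
    err = curve.err[idx] if curve.err is not None else np.zeros_like(exp_s)
    n_ext = len(extrap_s)
    nan = np.full(n_ext, np.nan)
    return DistanceDistribution(
        r=stored.r, p=stored.p, perr=stored.perr,
        fit_s=np.concatenate([extrap_s, exp_s]),
        fit_iexp=np.concatenate([nan, iexp]),
        fit_err=np.concatenate([nan, err]),
        fit_ireg=np.concatenate([nan, exp_reg]),
        fit_iext=np.concatenate([extrap_i, exp_reg]),
        Rg=stored.Rg, I0=stored.I0, Dmax=stored.Dmax,
        software=stored.software,
    )


# ---------------------------------------------------------------------------
# models

def pdb2cif(model: AtomicModel, file: CifFile,
            ctx: ConversionContext | None = None) -> CifFile:
    """Insert a spatial model as a new MODEL block (sas_model + atom_site)."""
    ctx = _ctx(ctx)
    label = ctx.block or _next_label(file, "MODEL")
    block = file.ensure_block(label)
    _conflict(block, "atom_site", ctx)
    existing = [
        _scalar_int(b, "sas_model", "id") or 0 for b in _model_blocks(file)
        if b is not block
    ]
    model_id = max(existing, default=0) + 1
    encode_model(block, model, model_id)
    return file


def cif2pdb(file: CifFile, out_dir: str | Path | None = None,
            basename: str = "model") -> list[str]:
    """Extract every model to PDB text, one per MODEL block.

    When ``out_dir`` is given the texts are also written to
    ``<basename><id>.pdb`` files (the directory is created if missing).
    """
    texts = []
    for block in _model_blocks(file):
        model_id, model = decode_model(block)
        texts.append((model_id, write_pdb(model)))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for model_id, text in texts:
            (out_dir / f"{basename}{model_id}.pdb").write_text(text)
    return [t for _, t in texts]


# ---------------------------------------------------------------------------
# fits

def fit2cif(fit: ModelFit, file: CifFile,
            ctx: ConversionContext | None = None) -> CifFile:
    """Insert a model fit as a new FIT block.

    The experimental-error column of a ``.fir`` source is *not* stored —
    errors belong with the original curve in ``sas_scan_intensity``.  A
    fit with no model link attaches to the sole stored model when there is
    exactly one, and is left unlinked with a warning otherwise.
    """
    ctx = _ctx(ctx)
    model_ids = [
        _scalar_int(b, "sas_model", "id") or 0 for b in _model_blocks(file)
    ]
    model_id = fit.model_id
    if model_id is not None:
        if model_id not in model_ids:
            raise EntryError(f"fit references unknown model id {model_id}")
    elif len(model_ids) == 1:
        model_id = model_ids[0]
    else:
        warnings.warn("fit stored without a model link")
        model_id = 0
    label = ctx.block or _next_label(file, "FIT")
    block = file.ensure_block(label)
    _conflict(block, "sas_model_fitting", ctx)
    existing = [
        _scalar_int(b, "sas_model_fitting_details", "id") or 0
        for b in _fit_blocks(file) if b is not block
    ]
    encode_fit(block, fit, max(existing, default=0) + 1, model_id,
               unit=ctx.unit)
    return file


def cif2fit(file: CifFile, out_dir: str | Path | None = None,
            dialect: str = "fit", basename: str = "fit") -> list[str]:
    """Extract every fit, one ``.fit`` text per FIT block.

    The χ²/p-value statistics go into the header.  ``dialect="fir"``
    re-attaches experimental errors, which requires the fit grid to match
    the stored curve grid exactly.
    """
    texts = []
    curves = {i: decode_curve(b) for i, b in enumerate(_main_blocks(file))}
    for block in _fit_blocks(file):
        _, _, fit = decode_fit(block)
        if dialect == "fir":
            err = _recover_errors(fit, curves.values())
            if err is None:
                raise EntryError(
                    f"block {block.name}: experimental errors not "
                    "recoverable from sas_scan_intensity"
                )
            fit.err = err
        texts.append((block.name, write_fitfile(fit, dialect)))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ext = dialect
        for i, (_, text) in enumerate(texts, start=1):
            (out_dir / f"{basename}{i}.{ext}").write_text(text)
    return [t for _, t in texts]


def _recover_errors(fit: ModelFit,
                    curves: Iterable[ScatteringCurve | None]) -> np.ndarray | None:
    for curve in curves:
        if curve is None or curve.err is None or len(curve) < len(fit):
            continue
        idx = np.searchsorted(curve.s, fit.s)
        idx = np.clip(idx, 0, len(curve.s) - 1)
        if np.allclose(curve.s[idx], fit.s, rtol=1e-9, atol=0):
            return curve.err[idx]
    return None


# ---------------------------------------------------------------------------
# metadata

def cif2sub(file: CifFile) -> dict[str, str]:
    """All scalar metadata as ordered name → value text pairs.

    Loops are excluded; placeholders are skipped.  Names follow the
    ``<category-minus-sas>_<item>`` convention (``sas_sample.name`` →
    ``sample_name``), which :func:`collect` accepts back as configuration.
    """
    pairs: dict[str, str] = {}
    for block in file.blocks:
        for cat in block.categories:
            if cat.is_loop:
                continue
            prefix = cat.name[4:] if cat.name.startswith("sas_") else cat.name
            for item in cat.item_names:
                if item == "id":
                    continue
                text = cat.scalar(item)
                if text is not None:
                    pairs.setdefault(f"{prefix}_{item}", text)
    return pairs


def route_sub_key(key: str, registry: Registry | None = None
                  ) -> tuple[str, str] | None:
    """Map a cif2sub-style key back to (category, item), or None."""
    registry = registry or load_registry()
    low = key.lower()
    for cdef in registry.categories.values():
        if cdef.is_loop:
            continue
        prefix = cdef.name[4:] if cdef.name.startswith("sas_") else cdef.name
        if low.startswith(prefix + "_") and low[len(prefix) + 1:] in cdef.items:
            return cdef.name, low[len(prefix) + 1:]
    return None


def read_flat_config(text: str) -> dict[str, str]:
    """Parse flat ``name : value`` configuration text (cif2sub layout)."""
    pairs: dict[str, str] = {}
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        name, sep, value = line.partition(":")
        if not sep:
            continue
        pairs[name.strip()] = value.strip()
    return pairs


def write_flat_config(pairs: Mapping[str, str]) -> str:
    return "".join(f"{k} : {v}\n" for k, v in pairs.items())


# ---------------------------------------------------------------------------
# everything at once

@dataclass(frozen=True)
class ManifestEntry:
    kind: str          # dat | out | pdb | fit | sub
    path: Path | None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def _slug(text: str | None) -> str:
    if not text:
        return "entry"
    slug = re.sub(r"[^A-Za-z0-9._-]+", "_", text).strip("_")
    return slug or "entry"


def cif2all(file: CifFile, out_dir: str | Path) -> list[ManifestEntry]:
    """Extract every data product from a sasCIF file in one sweep.

    Runs the dat, out, pdb, fit and sub extractors, writing each product
    under ``out_dir`` (created if missing); a failing component becomes an
    error entry in the manifest while the others still run.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mains = _main_blocks(file)
    base = _slug(_scalar_text(mains[0], "sas_scan", "title") if mains else None)
    manifest: list[ManifestEntry] = []

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curves = cif2dat(file)
        for i, curve in enumerate(curves, start=1):
            name = f"{base}.dat" if i == 1 else f"{base}_{i}.dat"
            path = out_dir / name
            path.write_text(write_dat(curve))
            manifest.append(ManifestEntry("dat", path))
    except Exception as exc:  # noqa: BLE001 — per-component isolation
        manifest.append(ManifestEntry("dat", None, str(exc)))

    if any(b.get("sas_p_of_r") is not None for b in mains):
        try:
            dist = cif2out(file)
            path = out_dir / f"{base}.out"
            path.write_text(write_out(dist))
            manifest.append(ManifestEntry("out", path))
        except Exception as exc:  # noqa: BLE001
            manifest.append(ManifestEntry("out", None, str(exc)))

    if _model_blocks(file):
        try:
            cif2pdb(file, out_dir, basename=f"{base}_model")
            for block in _model_blocks(file):
                model_id = _scalar_int(block, "sas_model", "id")
                manifest.append(
                    ManifestEntry("pdb", out_dir / f"{base}_model{model_id}.pdb")
                )
        except Exception as exc:  # noqa: BLE001
            manifest.append(ManifestEntry("pdb", None, str(exc)))

    if _fit_blocks(file):
        try:
            cif2fit(file, out_dir, basename=f"{base}_fit")
            for i in range(1, len(_fit_blocks(file)) + 1):
                manifest.append(
                    ManifestEntry("fit", out_dir / f"{base}_fit{i}.fit")
                )
        except Exception as exc:  # noqa: BLE001
            manifest.append(ManifestEntry("fit", None, str(exc)))

    try:
        path = out_dir / f"{base}.sub"
        path.write_text(write_flat_config(cif2sub(file)))
        manifest.append(ManifestEntry("sub", path))
    except Exception as exc:  # noqa: BLE001
        manifest.append(ManifestEntry("sub", None, str(exc)))
    return manifest


def collect(dat: str | Path,
            out: str | Path | None = None,
            models: Sequence[tuple[str | Path, str | Path | None]] = (),
            config: Mapping[str, str] | str | Path | None = None,
            unit: str = "1/angstrom") -> CifFile:
    """Build a complete sasCIF entry from a legacy file set.

    ``dat`` (mandatory) is the experimental curve; ``out`` the optional
    distance distribution; ``models`` a sequence of ``(.pdb, .fit-or-None)``
    path pairs; ``config`` extra metadata, either a mapping or a path to a
    flat ``name : value`` file in the cif2sub layout.  Equivalent to
    chaining the individual insert converters.
    """
    dat = Path(dat)
    if not dat.exists():
        raise FileNotFoundError(f"mandatory scattering curve not found: {dat}")
    file = CifFile()
    ctx = ConversionContext(unit=unit)
    dat2cif(read_dat(dat.read_text()), file, ctx)
    if out is not None:
        out2cif(read_out(Path(out).read_text()), file, ctx)
    for pdb_path, fit_path in models:
        pdb2cif(read_pdb(Path(pdb_path).read_text()), file, ctx)
        if fit_path is not None:
            fit = read_fitfile(Path(fit_path).read_text())
            fit.model_id = max(
                _scalar_int(b, "sas_model", "id") or 0
                for b in _model_blocks(file)
            )
            fit2cif(fit, file, ctx)
    if config is not None:
        if not isinstance(config, Mapping):
            config = read_flat_config(Path(config).read_text())
        main = file.ensure_block("MAIN")
        registry = load_registry()
        routed: dict[str, dict[str, Any]] = {}
        for key, value in config.items():
            target = route_sub_key(key, registry)
            if target is None:
                warnings.warn(f"config key {key!r} matches no sasCIF item; skipped")
                continue
            cat, item = target
            routed.setdefault(cat, {})[item] = str(value)
        for cat, items in routed.items():
            cdef = registry.category(cat)
            if cdef is not None and "id" in cdef.items:
                items.setdefault("id", 1)
            _merge_scalar(main, cat, items)
    return file
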