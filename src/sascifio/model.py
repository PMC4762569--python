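"""The sasCIF entry model: category vocabulary, block structure, validation.

A sasCIF file organises one small-angle-scattering measurement (or a
series) into data blocks with fixed roles:

* ``MAIN`` — the experimental curve (``sas_scan``/``sas_scan_intensity``),
  sample, buffer, beamline and detector descriptions, the derived overall
  parameters (``sas_result``), the pair-distance distribution
  (``sas_p_of_R*``) and the bibliographic categories.  A concentration or
  contrast series stores several MAIN-family blocks in one file.
* ``MODEL`` — one per spatial model: ``sas_model`` metadata plus the
  PDBx ``atom_site`` coordinate loop.
* ``FIT`` — one per model-versus-data fit: ``sas_model_fitting_details``
  (reduced χ², correlation-map p value, the model link) and the
  ``sas_model_fitting`` intensity loop.

A category may occur only once per block, which is why every model and
every fit needs its own block.  Integer ids tie FIT blocks to MODEL blocks
(``sas_model_fitting_details.model_id`` → ``sas_model.id``).

:class:`SasEntry` is the semantic view of one measurement spanning those
blocks; :func:`assemble_entry` / :func:`split_entry` convert between the
entry and the block structure, and :func:`validate` checks a parsed file
against the category registry shipped as a YAML data asset.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Any, Iterable

import numpy as np
import yaml

from .cif import (
    Category,
    CifFile,
    CifValue,
    DataBlock,
    MISSING,
    ValueKind,
)
from .formats import (
    Atom,
    AtomicModel,
    DistanceDistribution,
    ModelFit,
    ScatteringCurve,
)

__all__ = [
    "EntryError",
    "CategoryDef",
    "ItemDef",
    "Registry",
    "load_registry",
    "Finding",
    "SampleDescription",
    "BufferDescription",
    "InstrumentDescription",
    "ScanDescription",
    "OverallParameters",
    "Citation",
    "ExternalRef",
    "SasEntry",
    "assemble_entry",
    "assemble_entries",
    "split_entry",
    "validate",
    "MAIN_BLOCK_RE",
    "MODEL_BLOCK_RE",
    "FIT_BLOCK_RE",
]

MAIN_BLOCK_RE = re.compile(r"^main(\d*)$", re.I)
MODEL_BLOCK_RE = re.compile(r"^model(\d*)$", re.I)
FIT_BLOCK_RE = re.compile(r"^fit(\d*)$", re.I)

UNITS = ("1/angstrom", "1/nm")


class EntryError(ValueError):
    """A sasCIF file cannot be interpreted as a consistent entry."""


# ---------------------------------------------------------------------------
# registry

@dataclass(frozen=True)
class ItemDef:
    name: str
    domain: Any  # "text" | "number" | {"enum": [...]}
    required: bool = False

    @property
    def enum(self) -> list[str] | None:
        if isinstance(self.domain, dict) and "enum" in self.domain:
            return list(self.domain["enum"])
        return None


@dataclass(frozen=True)
class CategoryDef:
    name: str
    items: dict[str, ItemDef]
    key: tuple[str, ...]
    is_loop: bool
    block: str
    parents: dict[str, str]  # item -> "category.item"
    provenance: str

    def item(self, name: str) -> ItemDef | None:
        return self.items.get(name.lower())


@dataclass(frozen=True)
class MetadataRoute:
    canonical: str
    aliases: tuple[str, ...]
    category: str
    item: str
    route: str


class Registry:
    """The sasCIF category vocabulary plus the .dat metadata routing table."""

    def __init__(self, raw: dict):
        self.categories: dict[str, CategoryDef] = {}
        for name, spec in raw["categories"].items():
            items = {}
            key = tuple(k.lower() for k in spec.get("key", ()))
            for iname, ispec in (spec.get("items") or {}).items():
                ispec = ispec or {}
                items[iname.lower()] = ItemDef(
                    name=iname.lower(),
                    domain=ispec.get("domain", "text"),
                    required=bool(ispec.get("required")) or iname.lower() in key,
                )
            self.categories[name.lower()] = CategoryDef(
                name=name.lower(),
                items=items,
                key=key,
                is_loop=bool(spec.get("loop")),
                block=spec.get("block", "MAIN"),
                parents={k.lower(): v.lower() for k, v in (spec.get("parents") or {}).items()},
                provenance=spec.get("provenance", "local"),
            )
        self.dat_metadata: list[MetadataRoute] = []
        for entry in raw.get("dat_metadata", ()):
            cat, _, item = entry["target"].partition(".")
            self.dat_metadata.append(MetadataRoute(
                canonical=entry["canonical"],
                aliases=tuple(a.lower() for a in entry.get("aliases", ())),
                category=cat.lower(),
                item=item.lower(),
                route=entry.get("route", "local"),
            ))

    def category(self, name: str) -> CategoryDef | None:
        return self.categories.get(name.lower())

    def metadata_route(self, name: str) -> MetadataRoute | None:
        low = re.sub(r"\s+", " ", name.strip().lower())
        for route in self.dat_metadata:
            if low == route.canonical.lower() or low in route.aliases:
                return route
        return None

    def route_for_item(self, category: str, item: str) -> MetadataRoute | None:
        for route in self.dat_metadata:
            if route.category == category.lower() and route.item == item.lower():
                return route
        return None


@lru_cache(maxsize=1)
def load_registry() -> Registry:
    text = (
        resources.files("sascifio").joinpath("data/sascif_categories.yaml").read_text()
    )
    return Registry(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# entry dataclasses

def _check_nonneg(obj, names: Iterable[str]) -> None:
    for n in names:
        v = getattr(obj, n)
        if v is None:
            continue
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{n} must be finite and non-negative, got {v}")


@dataclass
class SampleDescription:
    name: str | None = None
    concentration: float | None = None          # mg/ml
    extinction_coefficient: float | None = None
    partial_specific_volume: float | None = None
    molecular_mass: float | None = None         # kDa
    contrast: float | None = None
    deuteration_level: float | None = None
    sequence: str | None = None                 # one-letter code, optional


@dataclass
class BufferDescription:
    composition: str | None = None
    pH: float | None = None
    comment: str | None = None


@dataclass
class InstrumentDescription:
    beamline_name: str | None = None
    location: str | None = None
    source_type: str | None = None
    detector_name: str | None = None
    detector_type: str | None = None
    wavelength: float | None = None             # angstrom


@dataclass
class ScanDescription:
    title: str | None = None
    unit: str = "1/angstrom"
    storage_temperature: float | None = None    # Celsius
    cell_temperature: float | None = None
    number_of_frames: int | None = None

    def __post_init__(self):
        if self.unit not in UNITS:
            raise ValueError(f"momentum-transfer unit must be one of {UNITS}")


@dataclass
class OverallParameters:
    """Derived parameters: Rg, I(0), Dmax, molecular-mass estimates.

    All values must be finite and non-negative; no relation between Dmax
    and Rg is imposed.
    """

    rg_guinier: float | None = None
    rg_guinier_err: float | None = None
    i0_guinier: float | None = None
    i0_guinier_err: float | None = None
    rg_pr: float | None = None
    rg_pr_err: float | None = None
    i0_pr: float | None = None
    dmax: float | None = None
    mw_from_i0: float | None = None
    mw_from_porod: float | None = None
    mw_from_ab_initio: float | None = None
    porod_volume: float | None = None

    _FIELDS = (
        "rg_guinier", "rg_guinier_err", "i0_guinier", "i0_guinier_err",
        "rg_pr", "rg_pr_err", "i0_pr", "dmax",
        "mw_from_i0", "mw_from_porod", "mw_from_ab_initio", "porod_volume",
    )

    def __post_init__(self):
        _check_nonneg(self, self._FIELDS)


@dataclass
class Citation:
    title: str | None = None
    journal: str | None = None
    volume: str | None = None
    page_first: str | None = None
    page_last: str | None = None
    year: int | None = None
    pubmed: str | None = None
    doi: str | None = None
    authors: list[str] = field(default_factory=list)


@dataclass
class ExternalRef:
    db_name: str
    db_code: str


@dataclass
class SasEntry:
    """Semantic view of one SAS measurement across MAIN/MODEL/FIT blocks."""

    curve: ScatteringCurve
    distribution: DistanceDistribution | None = None
    results: OverallParameters | None = None
    sample: SampleDescription = field(default_factory=SampleDescription)
    buffer: BufferDescription = field(default_factory=BufferDescription)
    instrument: InstrumentDescription = field(default_factory=InstrumentDescription)
    scan: ScanDescription = field(default_factory=ScanDescription)
    models: list[tuple[AtomicModel, ModelFit | None]] = field(default_factory=list)
    citation: Citation | None = None
    refs: list[ExternalRef] = field(default_factory=list)

    def __post_init__(self):
        ids = [f.model_id for _, f in self.models if f is not None and f.model_id]
        if len(ids) != len(set(ids)):
            raise ValueError("fit model ids must be unique within the entry")


# ---------------------------------------------------------------------------
# value helpers

def fmt_num(x: Any) -> str:
    """Canonical numeric text: integers bare, floats as %.6e, str verbatim."""
    if isinstance(x, str):
        return x
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        return "%.6e" % float(x)
    raise TypeError(f"cannot format {x!r}")


def _opt(x: Any) -> CifValue:
    if x is None:
        return MISSING
    if isinstance(x, float) and math.isnan(x):
        return MISSING
    return CifValue.of(fmt_num(x))


def _merge_scalar(block: DataBlock, cat_name: str, items: dict[str, Any],
                  skip_none: bool = True, keep_existing: bool = False) -> None:
    """Merge scalar items into a category, creating it when needed.

    With ``keep_existing`` an item already present keeps its stored text
    (metadata routed verbatim from a .dat header wins over re-formatted
    entry fields).
    """
    existing = block.get(cat_name)
    cols: dict[str, list[CifValue]] = {}
    if existing is not None and not existing.is_loop:
        for item in existing.item_names:
            cols[item] = list(existing[item])
    for item, val in items.items():
        if val is None and skip_none:
            continue
        if keep_existing and item.lower() in cols:
            continue
        cols[item.lower()] = [val if isinstance(val, CifValue) else _opt(val)]
    if cols:
        block.add(Category(cat_name, cols))


def _scalar_text(block: DataBlock, cat: str, item: str) -> str | None:
    c = block.get(cat)
    return c.scalar(item) if c is not None else None


def _scalar_float(block: DataBlock, cat: str, item: str) -> float | None:
    t = _scalar_text(block, cat, item)
    if t is None:
        return None
    try:
        return float(t)
    except ValueError:
        raise EntryError(f"{cat}.{item}: not a number: {t!r}") from None


def _scalar_int(block: DataBlock, cat: str, item: str) -> int | None:
    v = _scalar_float(block, cat, item)
    return None if v is None else int(round(v))


def _loop_floats(cat: Category, item: str) -> np.ndarray | None:
    col = cat.get(item)
    if col is None:
        return None
    out = np.empty(len(col))
    any_value = False
    for i, v in enumerate(col):
        t = v.as_text()
        if t is None:
            out[i] = np.nan
        else:
            out[i] = float(t)
            any_value = True
    return out if any_value else None


# ---------------------------------------------------------------------------
# encoding: curve / distribution / model / fit -> categories

def encode_curve(block: DataBlock, curve: ScatteringCurve,
                 registry: Registry | None = None) -> None:
    """Write a curve into MAIN-family categories.

    Recognised metadata names route to their sas_scan / sas_sample items
    (values kept verbatim); unrecognised pairs go to the
    ``sas_scan_metadata`` passthrough loop.
    """
    registry = registry or load_registry()
    routed: dict[str, dict[str, Any]] = {}
    extra: list[tuple[str, str]] = []
    for name, value in curve.metadata.items():
        route = registry.metadata_route(name)
        if route is None:
            extra.append((name, value))
        else:
            routed.setdefault(route.category, {})[route.item] = value
    scan_items: dict[str, Any] = {"id": 1}
    scan_items.update(routed.pop("sas_scan", {}))
    if curve.unit is not None:
        scan_items.setdefault("unit", curve.unit)
    scan_items["momentum_transfer_min"] = float(curve.s[0])
    scan_items["momentum_transfer_max"] = float(curve.s[-1])
    _merge_scalar(block, "sas_scan", scan_items)
    for cat_name, items in routed.items():
        cdef = registry.category(cat_name)
        if cdef is not None and "id" in cdef.items:
            items.setdefault("id", 1)
        _merge_scalar(block, cat_name, items)
    n = len(curve)
    cols: dict[str, list[Any]] = {
        "id": [str(i + 1) for i in range(n)],
        "momentum_transfer": [fmt_num(float(v)) for v in curve.s],
        "intensity": [fmt_num(float(v)) for v in curve.I],
    }
    if curve.err is not None:
        cols["error"] = [fmt_num(float(v)) for v in curve.err]
    else:
        cols["error"] = [MISSING] * n
    block.add(Category("sas_scan_intensity", cols, is_loop=True))
    if extra:
        block.add(Category("sas_scan_metadata", {
            "id": [str(i + 1) for i in range(len(extra))],
            "name": [k for k, _ in extra],
            "value": [v for _, v in extra],
        }, is_loop=True))


def decode_curve(block: DataBlock, registry: Registry | None = None
                 ) -> ScatteringCurve | None:
    """Inverse of :func:`encode_curve`; None when the block has no curve."""
    registry = registry or load_registry()
    cat = block.get("sas_scan_intensity")
    if cat is None:
        return None
    s = _loop_floats(cat, "momentum_transfer")
    I = _loop_floats(cat, "intensity")
    if s is None or I is None:
        return None
    err = _loop_floats(cat, "error")  # None when every row is a placeholder
    metadata: dict[str, str] = {}
    for cat_name in ("sas_scan", "sas_sample"):
        c = block.get(cat_name)
        if c is None:
            continue
        for item in c.item_names:
            route = registry.route_for_item(cat_name, item)
            if route is not None:
                text = c.scalar(item)
                if text is not None:
                    metadata[route.canonical] = text
    meta_cat = block.get("sas_scan_metadata")
    if meta_cat is not None:
        for row in meta_cat.rows():
            name = row["name"].as_text()
            if name is not None:
                metadata[name] = row["value"].as_text("") or ""
    unit = _scalar_text(block, "sas_scan", "unit")
    return ScatteringCurve(s, I, err, metadata, unit)


def encode_distribution(block: DataBlock, dist: DistanceDistribution) -> None:
    """Write p(r), the regularized intensities and the detail scalars.

    Experimental intensities and errors are *not* duplicated here — they
    live in ``sas_scan_intensity``; the extrapolated-intensity loop keeps
    only (s, I_reg), where rows below the lowest stored momentum transfer
    of the curve represent the extrapolation towards s = 0.
    """
    _merge_scalar(block, "sas_p_of_r_details", {
        "id": 1,
        "software_p_of_r": dist.software,
        "dmax": float(dist.Dmax),
        "rg": float(dist.Rg),
        "i0": float(dist.I0),
    })
    n = len(dist.r)
    perr = dist.perr
    block.add(Category("sas_p_of_r", {
        "id": [str(i + 1) for i in range(n)],
        "r": [fmt_num(float(v)) for v in dist.r],
        "p": [fmt_num(float(v)) for v in dist.p],
        "p_error": ([fmt_num(float(v)) for v in perr] if perr is not None
                    else [MISSING] * n),
    }, is_loop=True))
    ireg = np.where(np.isnan(dist.fit_ireg), dist.fit_iext, dist.fit_ireg)
    m = len(dist.fit_s)
    block.add(Category("sas_p_of_r_extrapolated_intensity", {
        "id": [str(i + 1) for i in range(m)],
        "momentum_transfer": [fmt_num(float(v)) for v in dist.fit_s],
        "intensity_reg": [fmt_num(float(v)) for v in ireg],
    }, is_loop=True))


def encode_model(block: DataBlock, model: AtomicModel, model_id: int) -> None:
    _merge_scalar(block, "sas_model", {
        "id": model_id,
        "model_type": model.model_type,
        "software": model.software,
        "symmetry": model.symmetry,
        "bead_radius": model.bead_radius,
    })
    atoms = model.atoms
    block.add(Category("atom_site", {
        "group_pdb": [a.record for a in atoms],
        "id": [str(a.serial) for a in atoms],
        "label_atom_id": [a.name for a in atoms],
        "label_comp_id": [a.res_name for a in atoms],
        "auth_asym_id": [a.chain_id for a in atoms],
        "auth_seq_id": [str(a.res_seq) for a in atoms],
        "cartn_x": ["%.3f" % a.x for a in atoms],
        "cartn_y": ["%.3f" % a.y for a in atoms],
        "cartn_z": ["%.3f" % a.z for a in atoms],
        "occupancy": ["%.2f" % a.occupancy for a in atoms],
        "b_iso_or_equiv": ["%.2f" % a.b_factor for a in atoms],
        "type_symbol": [a.element or MISSING for a in atoms],
    }, is_loop=True))


def decode_model(block: DataBlock) -> tuple[int, AtomicModel]:
    cat = block.get("atom_site")
    model_id = _scalar_int(block, "sas_model", "id")
    if model_id is None:
        raise EntryError(f"block {block.name}: sas_model.id missing")
    atoms: list[Atom] = []
    if cat is not None:
        for row in cat.rows():
            atoms.append(Atom(
                record=row["group_pdb"].as_text("ATOM"),
                serial=int(row["id"].as_text("0")),
                name=row["label_atom_id"].as_text("") if "label_atom_id" in cat else "",
                res_name=row["label_comp_id"].as_text("") if "label_comp_id" in cat else "",
                chain_id=row["auth_asym_id"].as_text("A") if "auth_asym_id" in cat else "A",
                res_seq=int(float(row["auth_seq_id"].as_text("0"))) if "auth_seq_id" in cat else 0,
                x=float(row["cartn_x"].as_text("nan")),
                y=float(row["cartn_y"].as_text("nan")),
                z=float(row["cartn_z"].as_text("nan")),
                occupancy=float(row["occupancy"].as_text("1")) if "occupancy" in cat else 1.0,
                b_factor=float(row["b_iso_or_equiv"].as_text("0")) if "b_iso_or_equiv" in cat else 0.0,
                element=(row["type_symbol"].as_text("") or "") if "type_symbol" in cat else "",
            ))
    bead = _scalar_float(block, "sas_model", "bead_radius")
    return model_id, AtomicModel(
        atoms=atoms,
        model_type=_scalar_text(block, "sas_model", "model_type") or "atomic",
        symmetry=_scalar_text(block, "sas_model", "symmetry"),
        bead_radius=bead,
        software=_scalar_text(block, "sas_model", "software"),
    )


def encode_fit(block: DataBlock, fit: ModelFit, fit_id: int, model_id: int,
               unit: str | None = None) -> None:
    """Write one fit into a FIT block.

    Experimental errors are never stored here; they belong with the
    original curve in ``sas_scan_intensity``.
    """
    _merge_scalar(block, "sas_model_fitting_details", {
        "id": fit_id,
        "model_id": model_id,
        "chi_square": fit.chi2_reduced,
        "p_value": fit.cormap_p,
        "unit": unit,
    })
    n = len(fit)
    block.add(Category("sas_model_fitting", {
        "id": [str(i + 1) for i in range(n)],
        "fitting_id": [str(fit_id)] * n,
        "momentum_transfer": [fmt_num(float(v)) for v in fit.s],
        "intensity": [fmt_num(float(v)) for v in fit.Iexp],
        "fit": [fmt_num(float(v)) for v in fit.Ifit],
    }, is_loop=True))


def decode_fit(block: DataBlock) -> tuple[int, int, ModelFit]:
    cat = block.get("sas_model_fitting")
    if cat is None:
        raise EntryError(f"block {block.name}: sas_model_fitting loop missing")
    s = _loop_floats(cat, "momentum_transfer")
    iexp = _loop_floats(cat, "intensity")
    ifit = _loop_floats(cat, "fit")
    if s is None or iexp is None or ifit is None:
        raise EntryError(f"block {block.name}: incomplete fit table")
    fit_id = _scalar_int(block, "sas_model_fitting_details", "id") or 0
    model_id = _scalar_int(block, "sas_model_fitting_details", "model_id")
    if model_id is None:
        raise EntryError(
            f"block {block.name}: sas_model_fitting_details.model_id missing"
        )
    fit = ModelFit(
        s, iexp, ifit,
        chi2_reduced=_scalar_float(block, "sas_model_fitting_details", "chi_square"),
        cormap_p=_scalar_float(block, "sas_model_fitting_details", "p_value"),
        model_id=model_id,
    )
    return fit_id, model_id, fit


# ---------------------------------------------------------------------------
# assemble / split

def _encode_main(block: DataBlock, entry: SasEntry, registry: Registry) -> None:
    encode_curve(block, entry.curve, registry)
    scan = entry.scan
    _merge_scalar(block, "sas_scan", {
        "title": scan.title,
        "unit": scan.unit,
        "storage_temperature": scan.storage_temperature,
        "cell_temperature": scan.cell_temperature,
        "number_of_frames": scan.number_of_frames,
    }, keep_existing=True)
    sam = entry.sample
    _merge_scalar(block, "sas_sample", {
        "id": 1,
        "name": sam.name,
        "specimen_concentration": sam.concentration,
        "extinction_coefficient": sam.extinction_coefficient,
        "partial_specific_volume": sam.partial_specific_volume,
        "molecular_mass": sam.molecular_mass,
        "contrast": sam.contrast,
        "deuteration_level": sam.deuteration_level,
        "entity_id": 1 if sam.sequence else None,
    }, keep_existing=True)
    buf = entry.buffer
    if buf.composition is not None or buf.pH is not None or buf.comment is not None:
        _merge_scalar(block, "sas_buffer", {
            "id": 1, "composition": buf.composition, "ph": buf.pH,
            "comment": buf.comment,
        })
    ins = entry.instrument
    if any(v is not None for v in (ins.beamline_name, ins.location,
                                   ins.source_type, ins.wavelength)):
        _merge_scalar(block, "sas_beam", {
            "id": 1, "beamline_name": ins.beamline_name,
            "location": ins.location, "type_of_source": ins.source_type,
            "radiation_wavelength": ins.wavelength,
        })
    if ins.detector_name is not None or ins.detector_type is not None:
        _merge_scalar(block, "sas_detc", {
            "id": 1, "name": ins.detector_name, "type": ins.detector_type,
        })
    res = entry.results
    if res is not None:
        _merge_scalar(block, "sas_result", {
            "id": 1,
            "rg_from_guinier": res.rg_guinier,
            "rg_from_guinier_error": res.rg_guinier_err,
            "i0_from_guinier": res.i0_guinier,
            "i0_from_guinier_error": res.i0_guinier_err,
            "rg_from_pr": res.rg_pr,
            "rg_from_pr_error": res.rg_pr_err,
            "i0_from_pr": res.i0_pr,
            "dmax": res.dmax,
            "mw_from_i0": res.mw_from_i0,
            "mw_from_porod_volume": res.mw_from_porod,
            "mw_from_ab_initio_volume": res.mw_from_ab_initio,
            "porod_volume": res.porod_volume,
        })
    if entry.distribution is not None:
        encode_distribution(block, entry.distribution)
    if sam.sequence:
        block.add(Category("entity", {
            "id": ["1"], "type": ["polymer"],
            "pdbx_description": [sam.name or MISSING],
        }, is_loop=True))
        block.add(Category("entity_poly", {
            "entity_id": ["1"], "type": ["polypeptide(L)"],
            "pdbx_seq_one_letter_code": [sam.sequence],
        }, is_loop=True))
    if entry.refs:
        block.add(Category("struct_ref", {
            "id": [str(i + 1) for i in range(len(entry.refs))],
            "db_name": [r.db_name for r in entry.refs],
            "db_code": [r.db_code for r in entry.refs],
            "entity_id": ["1"] * len(entry.refs),
        }, is_loop=True))
    cit = entry.citation
    if cit is not None:
        _merge_scalar(block, "citation", {
            "id": 1, "title": cit.title, "journal_abbrev": cit.journal,
            "journal_volume": cit.volume, "page_first": cit.page_first,
            "page_last": cit.page_last, "year": cit.year,
            "pdbx_database_id_pubmed": cit.pubmed,
            "pdbx_database_id_doi": cit.doi,
        })
        if cit.authors:
            block.add(Category("citation_author", {
                "citation_id": ["1"] * len(cit.authors),
                "name": list(cit.authors),
                "ordinal": [str(i + 1) for i in range(len(cit.authors))],
            }, is_loop=True))


def block_label(kind: str, index: int) -> str:
    """MAIN/MODEL/FIT for the first of a kind, MAIN2/MODEL2/... after."""
    return kind if index == 1 else f"{kind}{index}"


def assemble_entries(entries: list[SasEntry]) -> CifFile:
    """Build a sasCIF file from one or more entries (a measurement series).

    Blocks are labelled MAIN, MAIN2, …; each model gets its own MODEL[i]
    block and each fit its own FIT[i] block, linked by integer ids.
    """
    registry = load_registry()
    file = CifFile()
    main_i = model_i = fit_i = 0
    model_blocks: list[DataBlock] = []
    fit_blocks: list[DataBlock] = []
    for entry in entries:
        main_i += 1
        block = DataBlock(block_label("MAIN", main_i))
        _encode_main(block, entry, registry)
        file.blocks.append(block)
        for model, fit in entry.models:
            model_i += 1
            mblock = DataBlock(block_label("MODEL", model_i))
            encode_model(mblock, model, model_i)
            model_blocks.append(mblock)
            if fit is not None:
                fit_i += 1
                target = fit.model_id if fit.model_id is not None else model_i
                if target > model_i or target < 1:
                    raise EntryError(
                        f"fit references unknown model id {target}"
                    )
                fblock = DataBlock(block_label("FIT", fit_i))
                encode_fit(fblock, fit, fit_i, target, unit=entry.scan.unit)
                fit_blocks.append(fblock)
    file.blocks.extend(model_blocks)
    file.blocks.extend(fit_blocks)
    return file


def assemble_entry(entry: SasEntry) -> CifFile:
    """Build a sasCIF file for a single entry; see :func:`assemble_entries`."""
    return assemble_entries([entry])


def _decode_distribution(block: DataBlock, curve: ScatteringCurve | None
                         ) -> DistanceDistribution | None:
    pr = block.get("sas_p_of_r")
    if pr is None:
        return None
    r = _loop_floats(pr, "r")
    p = _loop_floats(pr, "p")
    perr = _loop_floats(pr, "p_error")
    ext = block.get("sas_p_of_r_extrapolated_intensity")
    if ext is not None:
        fs = _loop_floats(ext, "momentum_transfer")
        fi = _loop_floats(ext, "intensity_reg")
    else:
        fs = np.array([])
        fi = np.array([])
    nan = np.full(len(fs), np.nan)
    iexp = nan.copy()
    ierr = nan.copy()
    if curve is not None and curve.err is not None:
        # rows on the stored grid that coincide with experimental points
        idx = np.searchsorted(curve.s, fs)
        idx = np.clip(idx, 0, len(curve.s) - 1)
        close = np.abs(curve.s[idx] - fs) <= 1e-9 * np.maximum(1.0, np.abs(fs))
        iexp[close] = curve.I[idx[close]]
        ierr[close] = curve.err[idx[close]]
    ireg = np.where(np.isnan(iexp), np.nan, fi)
    dmax = _scalar_float(block, "sas_p_of_r_details", "dmax")
    rg = _scalar_float(block, "sas_p_of_r_details", "rg")
    i0 = _scalar_float(block, "sas_p_of_r_details", "i0")
    if dmax is None or rg is None or i0 is None:
        raise EntryError(
            f"block {block.name}: sas_p_of_R_details must provide Dmax, Rg and I0"
        )
    return DistanceDistribution(
        r=r, p=p, perr=perr, fit_s=fs, fit_iexp=iexp, fit_err=ierr,
        fit_ireg=ireg, fit_iext=fi, Rg=rg, I0=i0, Dmax=dmax,
        software=_scalar_text(block, "sas_p_of_r_details", "software_p_of_r"),
    )


def _decode_main(block: DataBlock, registry: Registry) -> SasEntry:
    curve = decode_curve(block, registry)
    if curve is None:
        raise EntryError(f"block {block.name}: no sas_scan_intensity data")
    scan = ScanDescription(
        title=_scalar_text(block, "sas_scan", "title"),
        unit=_scalar_text(block, "sas_scan", "unit") or "1/angstrom",
        storage_temperature=_scalar_float(block, "sas_scan", "storage_temperature"),
        cell_temperature=_scalar_float(block, "sas_scan", "cell_temperature"),
        number_of_frames=_scalar_int(block, "sas_scan", "number_of_frames"),
    )
    seq = None
    ep = block.get("entity_poly")
    if ep is not None and ep.n_rows:
        seq = next(iter(ep.rows()))["pdbx_seq_one_letter_code"].as_text()
    sample = SampleDescription(
        name=_scalar_text(block, "sas_sample", "name"),
        concentration=_scalar_float(block, "sas_sample", "specimen_concentration"),
        extinction_coefficient=_scalar_float(block, "sas_sample", "extinction_coefficient"),
        partial_specific_volume=_scalar_float(block, "sas_sample", "partial_specific_volume"),
        molecular_mass=_scalar_float(block, "sas_sample", "molecular_mass"),
        contrast=_scalar_float(block, "sas_sample", "contrast"),
        deuteration_level=_scalar_float(block, "sas_sample", "deuteration_level"),
        sequence=seq,
    )
    buffer = BufferDescription(
        composition=_scalar_text(block, "sas_buffer", "composition"),
        pH=_scalar_float(block, "sas_buffer", "ph"),
        comment=_scalar_text(block, "sas_buffer", "comment"),
    )
    instrument = InstrumentDescription(
        beamline_name=_scalar_text(block, "sas_beam", "beamline_name"),
        location=_scalar_text(block, "sas_beam", "location"),
        source_type=_scalar_text(block, "sas_beam", "type_of_source"),
        detector_name=_scalar_text(block, "sas_detc", "name"),
        detector_type=_scalar_text(block, "sas_detc", "type"),
        wavelength=_scalar_float(block, "sas_beam", "radiation_wavelength"),
    )
    results = None
    if block.get("sas_result") is not None:
        results = OverallParameters(
            rg_guinier=_scalar_float(block, "sas_result", "rg_from_guinier"),
            rg_guinier_err=_scalar_float(block, "sas_result", "rg_from_guinier_error"),
            i0_guinier=_scalar_float(block, "sas_result", "i0_from_guinier"),
            i0_guinier_err=_scalar_float(block, "sas_result", "i0_from_guinier_error"),
            rg_pr=_scalar_float(block, "sas_result", "rg_from_pr"),
            rg_pr_err=_scalar_float(block, "sas_result", "rg_from_pr_error"),
            i0_pr=_scalar_float(block, "sas_result", "i0_from_pr"),
            dmax=_scalar_float(block, "sas_result", "dmax"),
            mw_from_i0=_scalar_float(block, "sas_result", "mw_from_i0"),
            mw_from_porod=_scalar_float(block, "sas_result", "mw_from_porod_volume"),
            mw_from_ab_initio=_scalar_float(block, "sas_result", "mw_from_ab_initio_volume"),
            porod_volume=_scalar_float(block, "sas_result", "porod_volume"),
        )
    citation = None
    if block.get("citation") is not None:
        authors = []
        ca = block.get("citation_author")
        if ca is not None:
            authors = [row["name"].as_text("") or "" for row in ca.rows()]
        citation = Citation(
            title=_scalar_text(block, "citation", "title"),
            journal=_scalar_text(block, "citation", "journal_abbrev"),
            volume=_scalar_text(block, "citation", "journal_volume"),
            page_first=_scalar_text(block, "citation", "page_first"),
            page_last=_scalar_text(block, "citation", "page_last"),
            year=_scalar_int(block, "citation", "year"),
            pubmed=_scalar_text(block, "citation", "pdbx_database_id_pubmed"),
            doi=_scalar_text(block, "citation", "pdbx_database_id_doi"),
            authors=authors,
        )
    refs = []
    sr = block.get("struct_ref")
    if sr is not None:
        for row in sr.rows():
            refs.append(ExternalRef(
                db_name=row["db_name"].as_text("") or "",
                db_code=row["db_code"].as_text("") or "",
            ))
    return SasEntry(
        curve=curve,
        distribution=_decode_distribution(block, curve),
        results=results,
        sample=sample,
        buffer=buffer,
        instrument=instrument,
        scan=scan,
        citation=citation,
        refs=refs,
    )


def split_entry(file: CifFile) -> list[SasEntry]:
    """Decompose a sasCIF file into entries; inverse of assembly.

    Each MAIN-family block roots one :class:`SasEntry`.  MODEL and FIT
    blocks are attached through their integer id links; models and their
    fits are attached to the first entry.  Dangling links raise
    :class:`EntryError` listing the offenders.
    """
    registry = load_registry()
    entries: list[SasEntry] = []
    models: dict[int, AtomicModel] = {}
    fits: list[tuple[int, int, ModelFit]] = []
    for block in file.blocks:
        name = block.name
        if MAIN_BLOCK_RE.match(name):
            entries.append(_decode_main(block, registry))
        elif MODEL_BLOCK_RE.match(name):
            model_id, model = decode_model(block)
            if model_id in models:
                raise EntryError(f"duplicate sas_model.id {model_id}")
            models[model_id] = model
        elif FIT_BLOCK_RE.match(name):
            fits.append(decode_fit(block))
        # other blocks are ignored (foreign data is preserved by the caller)
    if not entries:
        raise EntryError("no MAIN-family data block found")
    dangling = sorted({mid for _, mid, _ in fits} - set(models))
    if dangling:
        raise EntryError(
            "fit blocks reference missing model id(s): "
            + ", ".join(str(d) for d in dangling)
        )
    fitted: dict[int, ModelFit] = {}
    for _, model_id, fit in sorted(fits, key=lambda t: t[0]):
        if model_id in fitted:
            raise EntryError(f"model id {model_id} has more than one fit")
        fitted[model_id] = fit
    entries[0].models = [
        (models[mid], fitted.get(mid)) for mid in sorted(models)
    ]
    return entries


# ---------------------------------------------------------------------------
# validation

@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    block: str
    category: str
    message: str

    def __str__(self) -> str:
        return f"[{self.severity}] {self.block}/{self.category}: {self.message}"


def validate(file: CifFile, registry: Registry | None = None) -> list[Finding]:
    """Check a parsed file against the category registry.

    Findings, never exceptions: unknown categories/items warn (they are
    preserved on round trip), missing key items, broken enumerations,
    non-numeric values in number items, dangling parent links and a
    non-monotone ``sas_scan_intensity`` grid are errors.
    """
    registry = registry or load_registry()
    findings: list[Finding] = []

    def err(block: str, cat: str, msg: str) -> None:
        findings.append(Finding("error", block, cat, msg))

    def warn(block: str, cat: str, msg: str) -> None:
        findings.append(Finding("warning", block, cat, msg))

    # collect referencable key values: category -> item -> set of texts
    key_values: dict[str, dict[str, set[str]]] = {}
    for block in file.blocks:
        for cat in block.categories:
            for item in cat.item_names:
                texts = {v.as_text() for v in cat[item]} - {None}
                key_values.setdefault(cat.name, {}).setdefault(item, set()).update(
                    texts  # type: ignore[arg-type]
                )

    for block in file.blocks:
        for cat in block.categories:
            cdef = registry.category(cat.name)
            if cdef is None:
                warn(block.name, cat.name, "category not in the sasCIF registry")
                continue
            for item in cat.item_names:
                idef = cdef.item(item)
                if idef is None:
                    warn(block.name, cat.name,
                         f"item {item} not in the registry (preserved verbatim)")
                    continue
                enum = idef.enum
                for v in cat[item]:
                    text = v.as_text()
                    if text is None:
                        continue
                    if enum is not None and text not in enum:
                        err(block.name, cat.name,
                            f"{item} value {text!r} not in {enum}")
                        break
                    if idef.domain == "number":
                        try:
                            float(text)
                        except ValueError:
                            err(block.name, cat.name,
                                f"{item} value {text!r} is not a number")
                            break
            for req in cdef.key:
                if req not in cat:
                    err(block.name, cat.name, f"key item {req} missing")
            for item, idef in cdef.items.items():
                if idef.required and item not in cdef.key and item not in cat:
                    err(block.name, cat.name, f"required item {item} missing")
            for child_item, parent in cdef.parents.items():
                if child_item not in cat:
                    continue
                pcat, _, pitem = parent.partition(".")
                available = key_values.get(pcat, {}).get(pitem, set())
                for v in cat[child_item]:
                    text = v.as_text()
                    if text is not None and text not in available:
                        err(block.name, cat.name,
                            f"{child_item}={text} has no parent {parent}")
                        break
            if cat.name == "sas_scan_intensity":
                s = _loop_floats(cat, "momentum_transfer")
                if s is not None and s.size > 1 and not np.all(np.diff(s) > 0):
                    err(block.name, cat.name,
                        "momentum_transfer column is not strictly increasing")
    return findings
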