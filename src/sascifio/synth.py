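"""Physically consistent synthetic SAS entries built on the homogeneous sphere.

The sphere is the one scattering body for which every quantity the toolkit
handles has a closed form, which makes the whole conversion chain testable
against analytic ground truth:

* intensity  I(s) = I(0) · [3 (sin sR − sR cos sR) / (sR)³]²,
* distance distribution  p(r) ∝ r² (1 − 3r/4R + r³/16R³) on [0, 2R],
* radius of gyration  Rg = R √(3/5),  maximum dimension  Dmax = 2R,
* first intensity zero near s = 4.4934/R (first root of tan x = x).

:func:`generate_entry` writes a complete legacy file set — a noisy ``.dat``
curve, a ``.out`` distribution with regularized fit and extrapolation to
s = 0, a bead-model ``.pdb`` sampled uniformly inside the sphere, a
``.fit`` of the noise-free curve against the noisy one, and a flat-text
metadata config — plus a ground-truth record.  Identical seeds give
byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats import (
    Atom,
    AtomicModel,
    DistanceDistribution,
    ModelFit,
    ScatteringCurve,
    write_dat,
    write_fitfile,
    write_out,
    write_pdb,
)
from .model import (
    BufferDescription,
    InstrumentDescription,
    OverallParameters,
    SampleDescription,
    SasEntry,
    ScanDescription,
)

__all__ = [
    "SphereTruth",
    "sphere_intensity",
    "sphere_p_of_r",
    "guinier_rg",
    "make_curve",
    "make_distribution",
    "make_bead_model",
    "make_fit",
    "make_entry",
    "generate_entry",
    "GeneratedEntry",
    "FIRST_ZERO_X",
]

#: first positive root of tan(x) = x — location of the first intensity zero
FIRST_ZERO_X = 4.493409457909064


@dataclass(frozen=True)
class SphereTruth:
    """Ground truth for one synthetic sphere measurement.

    ``noise`` is the fractional Gaussian noise level: σI(s) = noise·I(s).
    """

    R: float = 50.0          # sphere radius, angstrom
    I0: float = 1000.0       # forward scattering, arbitrary units
    noise: float = 0.01
    seed: int = 42

    def __post_init__(self):
        if self.R <= 0:
            raise ValueError("sphere radius must be positive")
        if self.noise < 0:
            raise ValueError("noise level must be non-negative")

    @property
    def Rg(self) -> float:
        return self.R * math.sqrt(3.0 / 5.0)

    @property
    def Dmax(self) -> float:
        return 2.0 * self.R


def sphere_intensity(R: float, I0: float, s_grid) -> np.ndarray:
    """Scattering intensity of a homogeneous sphere of radius *R*.

    The s → 0 limit (form factor 1) is taken analytically; a short series
    is used below x = sR ≈ 10⁻⁴ to avoid cancellation.
    """
    if R <= 0:
        raise ValueError("sphere radius must be positive")
    s = np.asarray(s_grid, dtype=float)
    if np.any(s < 0):
        raise ValueError("momentum transfer must be non-negative")
    x = s * R
    small = x < 1e-4
    xs = np.where(small, 1.0, x)
    form = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    form = np.where(small, 1.0 - x**2 / 10.0, form)
    return I0 * form**2


def sphere_p_of_r(R: float, r_grid, I0: float = 1.0) -> np.ndarray:
    """Pair-distance distribution of the sphere on 0 ≤ r ≤ 2R.

    Normalised with the convention I(0) = 4π ∫ p(r) dr, so the analytic
    ∫ r² γ₀ dr = R³/3 fixes the prefactor; the second-moment Rg equals
    R√(3/5) by construction.
    """
    if R <= 0:
        raise ValueError("sphere radius must be positive")
    r = np.asarray(r_grid, dtype=float)
    if np.any(r > 2 * R * (1 + 1e-12)) or np.any(r < 0):
        raise ValueError("r grid must lie within [0, 2R]")
    c = 3.0 * I0 / (4.0 * math.pi * R**3)
    return c * r**2 * (1.0 - 0.75 * r / R + r**3 / (16.0 * R**3))


def guinier_rg(curve: ScatteringCurve, s_rg_max: float = 1.3,
               max_iter: int = 50) -> tuple[float, float]:
    """Guinier estimates (Rg, I(0)) from the low-angle part of a curve.

    Fits ln I against s² over the window s·Rg ≤ *s_rg_max*, iterating the
    window to self-consistency.  The fit is second order in s² (a
    curvature-corrected Guinier fit): Rg comes from the linear
    coefficient and I(0) from the intercept, so a pure Gaussian
    I(0)·exp(−Rg²s²/3) is recovered exactly and the systematic bias a
    plain line fit picks up from compact bodies (≈ +2 % for a sphere at
    s·Rg ≤ 1.3) stays well below 1 %.  Raises ``ValueError`` when fewer
    than three usable points remain or the slope magnitude is
    non-positive (no Guinier decay).
    """
    s = np.asarray(curve.s, dtype=float)
    I = np.asarray(curve.I, dtype=float)
    usable = I > 0
    if usable.sum() < 3:
        raise ValueError("need at least three points with positive intensity")

    def fit(mask: np.ndarray) -> tuple[float, float]:
        x = s[mask] ** 2
        y = np.log(I[mask])
        order = 2 if mask.sum() > 3 else 1
        coef = np.polyfit(x, y, order)
        slope, intercept = coef[-2], coef[-1]
        if slope >= 0:
            raise ValueError("non-positive Guinier slope magnitude")
        return math.sqrt(-3.0 * slope), math.exp(intercept)

    seed_mask = usable.copy()
    seed_mask[np.cumsum(usable) > max(4, usable.sum() // 20)] = False
    rg, i0 = fit(seed_mask)
    for _ in range(max_iter):
        mask = usable & (s * rg <= s_rg_max)
        if mask.sum() < 3:
            raise ValueError("fewer than three points inside the Guinier window")
        new_rg, i0 = fit(mask)
        if abs(new_rg - rg) <= 1e-9 * rg:
            rg = new_rg
            break
        rg = new_rg
    return rg, i0


# ---------------------------------------------------------------------------
# building blocks

_DEF_METADATA_KEYS = ("Sample", "Concentration", "Storage temperature",
                      "Cell temperature", "Number of frames", "Unit")


def make_curve(truth: SphereTruth, n_points: int = 200,
               s_min: float = 0.01, s_max: float = 0.30,
               rng: np.random.Generator | None = None,
               metadata: dict[str, str] | None = None) -> ScatteringCurve:
    """Noisy sphere curve with canonical header metadata."""
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    s = np.linspace(s_min, s_max, n_points)
    clean = sphere_intensity(truth.R, truth.I0, s)
    err = truth.noise * clean
    noisy = clean + rng.normal(0.0, 1.0, n_points) * err
    if metadata is None:
        # scan-routed names first, then sample-routed: the order a curve
        # extracted from sasCIF comes back in, so .dat files round-trip
        # byte-identically
        metadata = {
            "Title": f"sphere_R{truth.R:g}",
            "Storage temperature": "4.0",
            "Cell temperature": "20.0",
            "Number of frames": "10",
            "Unit": "1/angstrom",
            "Sample": f"Synthetic sphere R={truth.R:g} A",
            "Concentration": "4.0",
        }
    return ScatteringCurve(s, noisy, err, dict(metadata), "1/angstrom")


def make_distribution(truth: SphereTruth, curve: ScatteringCurve,
                      n_r: int = 101, n_extrap: int = 10,
                      rebin_factor: int = 1) -> DistanceDistribution:
    """Sphere p(r) plus the noise-free regularized fit of the curve.

    ``rebin_factor`` > 1 stores the reciprocal fit on an accordingly
    coarser grid (every k-th experimental point), emulating the larger Δs
    an indirect-transform program may adopt for long curves.
    """
    r = np.linspace(0.0, truth.Dmax, n_r)
    p = sphere_p_of_r(truth.R, r, truth.I0)
    perr = truth.noise * np.maximum(p, 0.01 * p.max())
    sm = curve.s[::rebin_factor]
    clean = sphere_intensity(truth.R, truth.I0, sm)
    iexp = curve.I[::rebin_factor]
    ierr = (curve.err[::rebin_factor] if curve.err is not None
            else np.zeros_like(sm))
    s_ext = np.linspace(0.0, float(curve.s[0]), n_extrap, endpoint=False)
    i_ext = sphere_intensity(truth.R, truth.I0, s_ext)
    nan = np.full(n_extrap, np.nan)
    return DistanceDistribution(
        r=r, p=p, perr=perr,
        fit_s=np.concatenate([s_ext, sm]),
        fit_iexp=np.concatenate([nan, iexp]),
        fit_err=np.concatenate([nan, ierr]),
        fit_ireg=np.concatenate([nan, clean]),
        fit_iext=np.concatenate([i_ext, clean]),
        Rg=truth.Rg, I0=truth.I0, Dmax=truth.Dmax,
        software="sphere-synthesizer",
    )


def make_bead_model(truth: SphereTruth, n_beads: int = 200,
                    rng: np.random.Generator | None = None) -> AtomicModel:
    """Dummy-atom model: beads uniform in the sphere (rejection sampling)."""
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    coords = np.empty((n_beads, 3))
    filled = 0
    while filled < n_beads:
        draw = rng.uniform(-truth.R, truth.R, size=(2 * n_beads, 3))
        keep = draw[np.linalg.norm(draw, axis=1) <= truth.R]
        take = min(len(keep), n_beads - filled)
        coords[filled : filled + take] = keep[:take]
        filled += take
    bead_radius = truth.R * n_beads ** (-1.0 / 3.0)
    atoms = [
        Atom(record="ATOM", serial=i + 1, name="CA", res_name="DUM",
             chain_id="A", res_seq=i + 1,
             x=round(c[0], 3), y=round(c[1], 3), z=round(c[2], 3),
             occupancy=1.0, b_factor=20.0, element="C")
        for i, c in enumerate(coords)
    ]
    return AtomicModel(atoms=atoms, model_type="ab initio", symmetry="P1",
                       bead_radius=round(bead_radius, 3),
                       software="sphere-synthesizer")


def make_fit(truth: SphereTruth, curve: ScatteringCurve,
             model_id: int | None = None) -> ModelFit:
    """Noise-free model curve against the noisy data, with reduced χ².

    χ²_red = (1/(N−1)) Σ ((I_exp − I_fit)/σ)².
    """
    clean = sphere_intensity(truth.R, truth.I0, curve.s)
    err = curve.err if curve.err is not None else truth.noise * clean
    chi2 = float(np.sum(((curve.I - clean) / err) ** 2) / (len(curve) - 1))
    return ModelFit(curve.s, curve.I, clean, err=err,
                    chi2_reduced=round(chi2, 6), model_id=model_id)


def default_config(truth: SphereTruth, rg_guinier: float, i0_guinier: float
                   ) -> dict[str, str]:
    """Metadata config in the flat cif2sub layout."""
    return {
        "scan_title": f"sphere_R{truth.R:g}",
        "sample_molecular_mass": "14.3",
        "buffer_composition": "50 mM Tris-HCl, 150 mM NaCl",
        "buffer_ph": "7.5",
        "beam_beamline_name": "SYN-SAXS",
        "beam_location": "Synthetic Light Source",
        "beam_type_of_source": "X-ray synchrotron",
        "beam_radiation_wavelength": "1.24",
        "detc_name": "Counter 2M",
        "detc_type": "photon counting",
        "result_rg_from_guinier": "%.6e" % rg_guinier,
        "result_i0_from_guinier": "%.6e" % i0_guinier,
        "result_rg_from_pr": "%.6e" % truth.Rg,
        "result_i0_from_pr": "%.6e" % truth.I0,
        "result_dmax": "%.6e" % truth.Dmax,
    }


def make_entry(truth: SphereTruth, n_points: int = 200, n_models: int = 1,
               with_distribution: bool = True,
               rebin_factor: int = 1) -> SasEntry:
    """A complete in-memory :class:`~sascifio.model.SasEntry`."""
    rng = np.random.default_rng(truth.seed)
    curve = make_curve(truth, n_points=n_points, rng=rng)
    clean_curve = ScatteringCurve(
        curve.s, sphere_intensity(truth.R, truth.I0, curve.s))
    try:
        rg_g, i0_g = guinier_rg(clean_curve)
    except ValueError:  # grid too sparse for a Guinier window at this R
        rg_g = i0_g = None
    models = []
    for i in range(n_models):
        model = make_bead_model(truth, rng=rng)
        fit = make_fit(truth, curve, model_id=i + 1)
        models.append((model, fit))
    return SasEntry(
        curve=curve,
        distribution=(make_distribution(truth, curve, rebin_factor=rebin_factor)
                      if with_distribution else None),
        results=OverallParameters(
            rg_guinier=rg_g, i0_guinier=i0_g,
            rg_pr=truth.Rg, i0_pr=truth.I0, dmax=truth.Dmax,
        ),
        sample=SampleDescription(
            name=curve.metadata["Sample"], concentration=4.0,
            molecular_mass=14.3,
        ),
        buffer=BufferDescription(
            composition="50 mM Tris-HCl, 150 mM NaCl", pH=7.5),
        instrument=InstrumentDescription(
            beamline_name="SYN-SAXS", location="Synthetic Light Source",
            source_type="X-ray synchrotron", detector_name="Counter 2M",
            detector_type="photon counting", wavelength=1.24,
        ),
        scan=ScanDescription(
            title=f"sphere_R{truth.R:g}", unit="1/angstrom",
            storage_temperature=4.0, cell_temperature=20.0,
            number_of_frames=10,
        ),
        models=models,
    )


@dataclass(frozen=True)
class GeneratedEntry:
    """Paths of one generated legacy file set plus its ground truth."""

    truth: SphereTruth
    dat: Path
    out: Path | None
    models: tuple[tuple[Path, Path], ...]  # (.pdb, .fit) pairs
    config: Path
    truth_file: Path

    @property
    def files(self) -> list[Path]:
        paths = [self.dat, self.config, self.truth_file]
        if self.out is not None:
            paths.append(self.out)
        for pdb, fit in self.models:
            paths += [pdb, fit]
        return paths


def generate_entry(truth: SphereTruth, out_dir: str | Path,
                   n_points: int = 200, n_models: int = 1,
                   with_distribution: bool = True,
                   rebin_factor: int = 1) -> GeneratedEntry:
    """Write the legacy file set for one synthetic measurement.

    Produces ``<base>.dat``, ``<base>.out``, one ``(.pdb, .fit)`` pair per
    model, a flat metadata config and a ground-truth record.  The file set
    is a deterministic function of the truth record (seed included).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = f"sphere_R{truth.R:g}"
    rng = np.random.default_rng(truth.seed)
    curve = make_curve(truth, n_points=n_points, rng=rng)

    dat_path = out_dir / f"{base}.dat"
    dat_path.write_text(write_dat(curve))

    out_path = None
    if with_distribution:
        dist = make_distribution(truth, curve, rebin_factor=rebin_factor)
        out_path = out_dir / f"{base}.out"
        out_path.write_text(write_out(dist))

    model_paths = []
    for i in range(n_models):
        model = make_bead_model(truth, rng=rng)
        fit = make_fit(truth, curve)
        pdb_path = out_dir / f"{base}_model{i + 1}.pdb"
        fit_path = out_dir / f"{base}_fit{i + 1}.fit"
        pdb_path.write_text(write_pdb(model))
        fit_path.write_text(write_fitfile(fit, "fit"))
        model_paths.append((pdb_path, fit_path))

    clean_curve = ScatteringCurve(
        curve.s, sphere_intensity(truth.R, truth.I0, curve.s))
    rg_g, i0_g = guinier_rg(clean_curve)
    config_path = out_dir / f"{base}.cfg"
    config_lines = "".join(
        f"{k} : {v}\n" for k, v in default_config(truth, rg_g, i0_g).items()
    )
    config_path.write_text(config_lines)

    truth_path = out_dir / f"{base}.truth"
    truth_path.write_text(
        "".join(
            f"{k} : {v}\n"
            for k, v in {
                "R": "%.6e" % truth.R,
                "Rg": "%.6e" % truth.Rg,
                "Dmax": "%.6e" % truth.Dmax,
                "I0": "%.6e" % truth.I0,
                "noise": "%.6e" % truth.noise,
                "seed": str(truth.seed),
                "n_points": str(n_points),
            }.items()
        )
    )
    return GeneratedEntry(
        truth=truth, dat=dat_path, out=out_path,
        models=tuple(model_paths), config=config_path, truth_file=truth_path,
    )
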