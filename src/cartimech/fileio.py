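"""Readers and writers: NIfTI/TIFF image stacks and maps, YAML protocols
and parameter sets, CSV curves and composition tables.

Parameter maps are stored as three-channel float32 volumes
(values, adjusted R^2, mask) so a save/load cycle is lossless at float32
precision.  All tabular output is plain text (CSV/YAML/JSON) for
reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .composition import CompositionField, RationalDepthFit, WeightSet
from .constitutive import MaterialParameters
from .errors import FormatError
from .inverse import GlobalParameterSet, SampleData
from .relaxometry import AcquisitionProtocol, ParameterMap

_NIFTI_EXT = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(_NIFTI_EXT)


# --------------------------------------------------------------------------
# image stacks
# --------------------------------------------------------------------------

def save_stack(stack: np.ndarray, path) -> None:
    """Write a (timing, row, col) magnitude stack as NIfTI or TIFF."""
    path = Path(path)
    stack = np.asarray(stack, dtype=np.float32)
    if _is_nifti(path):
        # NIfTI convention: spatial axes first, timing last.
        nib.save(nib.Nifti1Image(np.transpose(stack, (1, 2, 0)),
                                 np.eye(4)), str(path))
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(str(path), stack)
    else:
        raise FormatError(f"unsupported stack format {path.suffix!r}")


def load_stack(path) -> np.ndarray:
    """Read a magnitude stack as (timing, row, col) float64."""
    path = Path(path)
    if _is_nifti(path):
        data = np.asanyarray(nib.load(str(path)).dataobj)
        if data.ndim != 3:
            raise FormatError("expected a 3-D stack")
        return np.transpose(data, (2, 0, 1)).astype(float)
    if path.suffix in (".tif", ".tiff"):
        data = tifffile.imread(str(path))
        if data.ndim != 3:
            raise FormatError("expected a multi-page TIFF")
        return data.astype(float)
    raise FormatError(f"unsupported stack format {path.suffix!r}")


def load_mask(path, shape=None) -> np.ndarray:
    """Read a binary mask (NIfTI or PNG/TIFF, nonzero = inside)."""
    path = Path(path)
    if _is_nifti(path):
        data = np.asanyarray(nib.load(str(path)).dataobj)
    elif path.suffix in (".png", ".tif", ".tiff"):
        if path.suffix == ".png":
            from PIL import Image
            data = np.asarray(Image.open(str(path)))
        else:
            data = tifffile.imread(str(path))
    else:
        raise FormatError(f"unsupported mask format {path.suffix!r}")
    data = np.squeeze(data)
    if data.ndim != 2:
        raise FormatError("mask must be 2-D")
    mask = data > 0
    if shape is not None and mask.shape != tuple(shape):
        raise FormatError(f"mask shape {mask.shape} does not match "
                          f"image shape {tuple(shape)}")
    return mask


# --------------------------------------------------------------------------
# parameter maps
# --------------------------------------------------------------------------

def save_map(pmap: ParameterMap, path) -> None:
    """Write a parameter map as a 3-channel (values, quality, mask)
    float32 NIfTI or TIFF."""
    path = Path(path)
    data = np.stack([pmap.values, pmap.quality,
                     pmap.mask.astype(float)], axis=-1).astype(np.float32)
    if _is_nifti(path):
        img = nib.Nifti1Image(data, np.eye(4))
        img.header["descrip"] = pmap.modality.encode()[:79]
        nib.save(img, str(path))
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(str(path), np.transpose(data, (2, 0, 1)),
                         description=pmap.modality)
    else:
        raise FormatError(f"unsupported map format {path.suffix!r}")


def load_map(path, modality: str | None = None) -> ParameterMap:
    """Read a parameter map saved by :func:`save_map`.

    A plain single-channel image is accepted as a bare values map: the
    mask defaults to all-true (with a warning) and the quality channel to
    NaN.
    """
    path = Path(path)
    stored = None
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        stored = str(img.header["descrip"].item().decode() or "") or None
    elif path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            stored = (tf.pages[0].description or None)
        if data.ndim == 3:
            data = np.transpose(data, (1, 2, 0))
    else:
        raise FormatError(f"unsupported map format {path.suffix!r}")
    modality = modality or stored
    if modality is None:
        raise FormatError("modality neither stored in the file nor given")
    data = np.squeeze(data)
    if data.ndim == 2:
        warnings.warn("no mask channel found; assuming all-true mask",
                      stacklevel=2)
        return ParameterMap(modality, data.astype(float),
                            np.full(data.shape, np.nan),
                            np.ones(data.shape, dtype=bool))
    if data.ndim != 3 or data.shape[-1] != 3:
        raise FormatError("expected a (row, col, 3) parameter-map volume")
    values, quality, mask = (data[..., i].astype(float) for i in range(3))
    return ParameterMap(modality, values, quality, mask > 0.5)


def map_to_csv(pmap: ParameterMap, path) -> None:
    """Dump masked pixels as CSV rows (row, col, value, adjusted_r2)."""
    rr, cc = np.nonzero(pmap.mask)
    pd.DataFrame({"row": rr, "col": cc, "value_ms": pmap.values[rr, cc],
                  "adjusted_r2": pmap.quality[rr, cc]}
                 ).to_csv(path, index=False)


# --------------------------------------------------------------------------
# YAML configuration objects
# --------------------------------------------------------------------------

def load_protocol(path) -> AcquisitionProtocol:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    try:
        return AcquisitionProtocol(
            modality=cfg["modality"],
            timing_values_ms=tuple(cfg["timings_ms"]),
            tr_ms=cfg.get("TR_ms"),
            te_cutoff_ms=cfg.get("TE_cutoff_ms", 60.0))
    except KeyError as e:
        raise FormatError(f"protocol file missing key {e}") from e


def save_protocol(protocol: AcquisitionProtocol, path) -> None:
    cfg = {"modality": protocol.modality,
           "timings_ms": list(protocol.timing_values_ms),
           "TR_ms": protocol.tr_ms, "TE_cutoff_ms": protocol.te_cutoff_ms}
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh)


def load_parameters(path) -> GlobalParameterSet:
    """Material constants and weight set from YAML."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    mat = MaterialParameters(**cfg.get("material", {}))
    wcfg = cfg.get("weights")
    if wcfg is None:
        weights = WeightSet.default()
    else:
        order = ("T1", "T1rho", "T2", "T2star")
        weights = WeightSet(
            fluid=tuple(float(wcfg["fluid"][m]) for m in order),
            collagen=tuple(float(wcfg["collagen"][m]) for m in order))
    return GlobalParameterSet(mat, weights)


def save_parameters(theta: GlobalParameterSet, path) -> None:
    order = ("T1", "T1rho", "T2", "T2star")
    cfg = {"material": asdict(theta.material),
           "weights": {
               "fluid": {m: float(w) for m, w in
                         zip(order, theta.weights.fluid)},
               "collagen": {m: float(w) for m, w in
                            zip(order, theta.weights.collagen)}}}
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def save_profile_fits(fits: dict, path) -> None:
    """Per-(constituent, modality) rational depth-fit coefficients."""
    cfg = {xi: {m: asdict(fit) for m, fit in fits[xi].items()}
           for xi in fits}
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def load_profile_fits(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return {xi: {m: RationalDepthFit(**coeffs)
                 for m, coeffs in cfg[xi].items()} for xi in cfg}


# --------------------------------------------------------------------------
# curves and composition tables
# --------------------------------------------------------------------------

def save_curve(strains, stress_mpa, path) -> None:
    pd.DataFrame({"strain": np.asarray(strains, dtype=float),
                  "nominal_stress_mpa": np.asarray(stress_mpa, dtype=float)}
                 ).to_csv(path, index=False)


def load_curve(path):
    df = pd.read_csv(path)
    for col in ("strain", "nominal_stress_mpa"):
        if col not in df.columns:
            raise FormatError(f"curve file missing column {col!r}")
    return (df["strain"].to_numpy(dtype=float),
            df["nominal_stress_mpa"].to_numpy(dtype=float))


def save_composition(comp: CompositionField, path) -> None:
    pd.DataFrame({"z": comp.z, "phi_f": comp.phi_f, "phi_co": comp.phi_co,
                  "phi_pg": comp.phi_pg}).to_csv(path, index=False)


def load_composition(path) -> CompositionField:
    df = pd.read_csv(path)
    for col in ("z", "phi_f", "phi_co", "phi_pg"):
        if col not in df.columns:
            raise FormatError(f"composition file missing column {col!r}")
    return CompositionField(df["z"].to_numpy(dtype=float),
                            df["phi_f"].to_numpy(dtype=float),
                            df["phi_co"].to_numpy(dtype=float),
                            df["phi_pg"].to_numpy(dtype=float))


def load_samples_manifest(path) -> list[SampleData]:
    """Sample manifest YAML: a list of entries with keys ``name``,
    ``profiles`` (YAML path), ``curve`` (CSV path), ``thickness_mm`` and
    optional ``n_layers``; relative paths resolve against the manifest."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    samples = []
    for entry in cfg["samples"]:
        fits = load_profile_fits(path.parent / entry["profiles"])
        strains, stress = load_curve(path.parent / entry["curve"])
        samples.append(SampleData(
            name=str(entry["name"]), profile_fits=fits,
            strains=tuple(strains), stress_mpa=tuple(stress),
            thickness_mm=float(entry.get("thickness_mm", 4.2)),
            n_layers=int(entry.get("n_layers", 12))))
    return samples
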