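"""On-disk formats: NIfTI subjects, JSON manifests, and checkpoints.

A phantom subject is stored as three NIfTI volumes — the image, a
bit-coded structure label map (each structure owns one bit, so overlapping
structures round-trip losslessly), and the general-model mask — plus a
manifest entry recording the subject id, generation seed, spacing and the
structure-code table.  Orientation is fixed to the package's axis
convention (axis 0 superior→inferior, axis 1 anterior→posterior, axis 2
left→right) with a diagonal affine carrying the spacing; this is asserted
on read.

Checkpoints are numpy ``.npz`` archives holding the architecture spec as a
JSON string, every parameter array, and a content digest that is
recomputed and verified on load.
"""

from __future__ import annotations

import json
import zipfile
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np

from .grids import Mask, PhantomSubject, StructureSet, Volume
from .network import ArchSpec, ModelState

STRUCTURE_BITS: Dict[str, int] = {
    "target": 1,
    "neighbor_sup": 2,
    "neighbor_post": 4,
    "ref_a": 8,
    "ref_b": 16,
}

MANIFEST_NAME = "manifest.json"


class CheckpointError(RuntimeError):
    """Raised for corrupt, truncated or mismatched checkpoint files."""


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def _spacing_from(img: nib.Nifti1Image, path: Path) -> Tuple[float, float, float]:
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-6):
        raise ValueError(f"{path}: non-diagonal affine; unsupported orientation")
    diag = np.diag(aff[:3, :3])
    if (diag <= 0).any():
        raise ValueError(f"{path}: axis flip in affine; expected the package's "
                         "fixed orientation (sup→inf, ant→post, left→right)")
    return tuple(float(v) for v in diag)


def subject_paths(out_dir: Path, subject_id: str) -> Dict[str, Path]:
    out_dir = Path(out_dir)
    return {
        "image": out_dir / f"{subject_id}_image.nii.gz",
        "labels": out_dir / f"{subject_id}_labels.nii.gz",
        "general": out_dir / f"{subject_id}_general.nii.gz",
    }


def write_subject(subject: PhantomSubject, out_dir) -> dict:
    """Write one subject's three NIfTI files; returns its manifest entry."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = subject_paths(out_dir, subject.subject_id)
    spacing = subject.volume.spacing
    aff = _affine(spacing)
    nib.save(nib.Nifti1Image(subject.volume.grid.astype(np.float32), aff), paths["image"])
    labels = np.zeros(subject.volume.shape, dtype=np.uint8)
    for name, bit in STRUCTURE_BITS.items():
        labels |= np.where(subject.structures[name].grid, np.uint8(bit), np.uint8(0))
    nib.save(nib.Nifti1Image(labels, aff), paths["labels"])
    nib.save(
        nib.Nifti1Image(subject.general_mask.grid.astype(np.uint8), aff), paths["general"]
    )
    return {
        "subject_id": subject.subject_id,
        "seed": subject.seed,
        "spacing": list(spacing),
        "structure_bits": STRUCTURE_BITS,
        "files": {k: p.name for k, p in paths.items()},
    }


def write_cohort(subjects: Sequence[PhantomSubject], out_dir) -> Path:
    """Write all subjects plus a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    entries = [write_subject(s, out_dir) for s in subjects]
    manifest = out_dir / MANIFEST_NAME
    manifest.write_text(json.dumps({"subjects": entries}, indent=2))
    return manifest


def read_subject(
    image_path, labels_path, general_path, structure_bits: Optional[Dict[str, int]] = None
) -> PhantomSubject:
    """Read one subject back; the mask round trip is bit-identical.

    Raises FileNotFoundError naming the missing path, ValueError for
    incongruent grids or undeclared label codes.
    """
    bits = dict(structure_bits or STRUCTURE_BITS)
    paths = {"image": Path(image_path), "labels": Path(labels_path), "general": Path(general_path)}
    for kind, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"missing {kind} file: {p}")
    img = nib.load(paths["image"])
    lab = nib.load(paths["labels"])
    gen = nib.load(paths["general"])
    spacing = _spacing_from(img, paths["image"])
    for kind, n in (("labels", lab), ("general", gen)):
        if n.shape != img.shape:
            raise ValueError(f"{paths[kind]}: grid {n.shape} incongruent with image {img.shape}")
        if not np.allclose(_spacing_from(n, paths[kind]), spacing, atol=1e-6):
            raise ValueError(f"{paths[kind]}: spacing differs from image")
    labels = np.asarray(lab.dataobj).astype(np.uint8)
    declared = 0
    for bit in bits.values():
        declared |= bit
    undeclared = np.unique(labels[(labels & ~np.uint8(declared)) != 0])
    if undeclared.size:
        raise ValueError(
            f"{paths['labels']}: label values with undeclared structure bits: "
            f"{sorted(int(v) for v in undeclared)} (declared bit mask {declared})"
        )
    masks = {
        name: Mask((labels & np.uint8(bit)) != 0, spacing) for name, bit in bits.items()
    }
    structures = StructureSet(**masks)
    general = Mask(np.asarray(gen.dataobj).astype(bool), spacing)
    volume = Volume(np.asarray(img.dataobj, dtype=np.float32), spacing)
    sid = Path(image_path).name.replace("_image.nii.gz", "").replace("_image.nii", "")
    return PhantomSubject(
        volume=volume, structures=structures, general_mask=general, subject_id=sid, seed=-1
    )


def read_cohort(data_dir) -> List[PhantomSubject]:
    """Read every subject listed in a directory's manifest."""
    data_dir = Path(data_dir)
    manifest = data_dir / MANIFEST_NAME
    if not manifest.exists():
        raise FileNotFoundError(f"missing manifest: {manifest}")
    meta = json.loads(manifest.read_text())
    subjects = []
    for entry in meta["subjects"]:
        files = entry["files"]
        s = read_subject(
            data_dir / files["image"],
            data_dir / files["labels"],
            data_dir / files["general"],
            structure_bits=entry.get("structure_bits"),
        )
        subjects.append(
            PhantomSubject(
                volume=s.volume,
                structures=s.structures,
                general_mask=s.general_mask,
                subject_id=entry["subject_id"],
                seed=entry.get("seed", -1),
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(state: ModelState, path) -> None:
    """Write arch spec (JSON), parameters and digest to an .npz archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        __arch__=np.str_(state.arch.to_json()),
        __digest__=np.str_(state.digest()),
        **{f"param/{k}": v for k, v in state.params.items()},
    )


def load_checkpoint(path, expect_arch: Optional[ArchSpec] = None) -> ModelState:
    """Load and verify a checkpoint.

    The digest is recomputed from the loaded parameters and must match the
    stored digest (corruption check); if ``expect_arch`` is given, any
    architecture mismatch is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing checkpoint: {path}")
    try:
        with np.load(path, allow_pickle=False) as data:
            arch = ArchSpec.from_json(str(data["__arch__"]))
            stored_digest = str(data["__digest__"])
            params = {
                k[len("param/") :]: np.asarray(data[k], dtype=np.float32)
                for k in data.files
                if k.startswith("param/")
            }
    except (zipfile.BadZipFile, OSError, KeyError, ValueError) as exc:
        raise CheckpointError(f"unreadable or truncated checkpoint {path}: {exc}") from exc
    state = ModelState(arch, params)
    if state.digest() != stored_digest:
        raise CheckpointError(f"digest mismatch in {path}: parameters corrupted")
    if expect_arch is not None and arch != expect_arch:
        raise CheckpointError(
            f"architecture mismatch: checkpoint {arch} vs requested {expect_arch}"
        )
    return state
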