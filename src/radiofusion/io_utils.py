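"""Dataset readers/writers, run configuration and checkpointing.

On-disk dialect
---------------
* images: 8-bit grayscale PNG (default) or NIfTI ``.nii.gz``; row-major,
  origin top-left (row = y, column = x);
* masks: 8-bit PNG with values {0, 255};
* ``manifest.csv``: sample_id, image_path, mask_path, label, is_labeled, split;
* ``expression.csv``: sample_id + gene_0001..gene_NNNN columns, one row per
  sample;
* checkpoints: ``.npz`` archive of named tensors + a JSON sidecar with the
  config hash and seed;
* screens/reports: JSON.

Every artifact embeds the seed and config hash that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .backbone import BackboneConfig
from .mean_teacher import ClassifierConfig, SemiTrainConfig
from .phantom import PhantomCohort, PhantomConfig, PhantomSample, config_as_dict
from .segnet import SegTrainConfig


class DataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_SECTIONS = {
    "data": PhantomConfig,
    "backbone": BackboneConfig,
    "classifier": ClassifierConfig,
    "seg_train": SegTrainConfig,
    "semi_train": SemiTrainConfig,
    "gene": None,   # plain dict: {k, scorer}
    "eval": None,   # plain dict: {threshold, kfold}
}

_GENE_DEFAULTS = {"k": 115, "scorer": "point_biserial"}
_EVAL_DEFAULTS = {"threshold": 0.5, "kfold": 5}


@dataclasses.dataclass
class RunConfig:
    data: PhantomConfig
    backbone: BackboneConfig
    classifier: ClassifierConfig
    seg_train: SegTrainConfig
    semi_train: SemiTrainConfig
    gene: dict
    eval: dict

    def as_dict(self) -> dict:
        out = {
            "data": config_as_dict(self.data),
            "backbone": dataclasses.asdict(self.backbone),
            "classifier": dataclasses.asdict(self.classifier),
            "seg_train": dataclasses.asdict(self.seg_train),
            "semi_train": dataclasses.asdict(self.semi_train),
            "gene": dict(self.gene),
            "eval": dict(self.eval),
        }
        for sec in ("backbone",):
            for k, v in out[sec].items():
                if isinstance(v, tuple):
                    out[sec][k] = list(v)
        return out

    def hash(self) -> str:
        return config_hash(self.as_dict())


def config_hash(d: dict) -> str:
    """Stable hash of a (nested) config dict; key order does not matter."""
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _build_section(cls, values: dict, section: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(values) - set(fields)
    if unknown:
        raise DataError(f"unknown keys in config section '{section}': {sorted(unknown)}")
    coerced = {}
    for k, v in values.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    return cls(**coerced)


def default_config() -> RunConfig:
    return RunConfig(data=PhantomConfig(), backbone=BackboneConfig(),
                     classifier=ClassifierConfig(), seg_train=SegTrainConfig(),
                     semi_train=SemiTrainConfig(), gene=dict(_GENE_DEFAULTS),
                     eval=dict(_EVAL_DEFAULTS))


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON run configuration; unknown keys are rejected."""
    if path is None:
        return default_config()
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise DataError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for sec, cls in _SECTIONS.items():
        vals = raw.get(sec, {})
        if cls is None:
            defaults = dict(_GENE_DEFAULTS if sec == "gene" else _EVAL_DEFAULTS)
            unknown = set(vals) - set(defaults)
            if unknown:
                raise DataError(f"unknown keys in config section '{sec}': {sorted(unknown)}")
            defaults.update(vals)
            kwargs[sec] = defaults
        else:
            kwargs[sec] = _build_section(cls, vals, sec)
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# Cohort writing / loading
# ---------------------------------------------------------------------------

def _save_png(path: Path, array01: np.ndarray):
    img = np.clip(np.round(array01 * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(img, mode="L").save(path)


def _load_image_file(path: Path) -> np.ndarray:
    if path.suffix == ".png":
        arr = np.asarray(Image.open(path), dtype=np.float32)
        return arr / 255.0
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        arr = np.asarray(nib.load(str(path)).dataobj, dtype=np.float32)
        lo, hi = float(arr.min()), float(arr.max())
        return (arr - lo) / (hi - lo) if hi > lo else arr * 0.0
    raise DataError(f"unsupported image format: {path}")


def write_cohort(cohort: PhantomCohort, out_dir: str | Path,
                 image_format: str = "png") -> Path:
    """Write images/masks plus manifest.csv and expression.csv."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    split_of = {}
    for name, idx in cohort.split.items():
        for i in idx:
            split_of[int(i)] = name
    rows = []
    for i, s in enumerate(cohort.samples):
        sid = f"sample_{i:05d}"
        if image_format == "png":
            ipath = out / "images" / f"{sid}.png"
            _save_png(ipath, s.image)
        elif image_format == "nifti":
            import nibabel as nib
            ipath = out / "images" / f"{sid}.nii.gz"
            nib.save(nib.Nifti1Image(s.image.astype(np.float32), np.eye(4)), str(ipath))
        else:
            raise DataError(f"unknown image format '{image_format}'")
        mpath = out / "masks" / f"{sid}.png"
        _save_png(mpath, s.mask.astype(np.float32))
        rows.append({"sample_id": sid,
                     "image_path": str(ipath.relative_to(out)),
                     "mask_path": str(mpath.relative_to(out)),
                     "label": int(s.label) if s.is_labeled else "",
                     "is_labeled": bool(s.is_labeled),
                     "split": split_of.get(i, "train_unlabeled")})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    expr = cohort.expression_matrix()
    cols = [f"gene_{j + 1:04d}" for j in range(expr.shape[1])]
    df = pd.DataFrame(expr, columns=cols)
    df.insert(0, "sample_id", [f"sample_{i:05d}" for i in range(len(cohort))])
    df.to_csv(out / "expression.csv", index=False)
    meta = {"seed": cohort.config.seed if cohort.config else None,
            "config": config_as_dict(cohort.config) if cohort.config else None,
            "config_hash": config_hash(config_as_dict(cohort.config)) if cohort.config else None}
    (out / "cohort.json").write_text(json.dumps(meta, indent=2))
    return out / "manifest.csv"


_REQUIRED_COLS = {"sample_id", "image_path", "mask_path", "label", "is_labeled", "split"}


def load_manifest(manifest_path: str | Path,
                  expression_path: str | Path | None = None) -> PhantomCohort:
    """Load a cohort from manifest.csv (+ expression.csv next to it)."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise DataError(f"manifest not found: {manifest_path}")
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    missing = _REQUIRED_COLS - set(df.columns)
    if missing:
        raise DataError(f"manifest missing columns: {sorted(missing)}")
    if expression_path is None:
        expression_path = base / "expression.csv"
    expr = None
    if Path(expression_path).exists():
        edf = pd.read_csv(expression_path)
        expr = edf.drop(columns=["sample_id"]).to_numpy(dtype=np.float32)
        if len(expr) != len(df):
            raise DataError("expression.csv row count does not match manifest")
    samples = []
    split: dict[str, list[int]] = {"train_labeled": [], "train_unlabeled": [], "test": []}
    for i, row in df.iterrows():
        image = _load_image_file(base / row["image_path"])
        mask_p = base / str(row["mask_path"])
        if isinstance(row["mask_path"], str) and mask_p.exists():
            mask = (_load_image_file(mask_p) >= 0.5).astype(np.uint8)
            if mask.shape != image.shape:
                raise DataError(f"row {i} ({row['sample_id']}): image {image.shape} "
                                f"vs mask {mask.shape} size mismatch")
        else:
            mask = np.zeros_like(image, dtype=np.uint8)
        is_labeled = bool(row["is_labeled"])
        label_raw = row["label"]
        if is_labeled and (pd.isna(label_raw) or label_raw == ""):
            raise DataError(f"row {i} ({row['sample_id']}) is labeled but has no label")
        label = int(label_raw) if not pd.isna(label_raw) and label_raw != "" else 0
        genes = expr[i] if expr is not None else np.zeros(0, dtype=np.float32)
        samples.append(PhantomSample(image=image.astype(np.float32), mask=mask,
                                     label=label, genes=genes, is_labeled=is_labeled))
        sp = str(row["split"])
        split.setdefault(sp, []).append(i)
    return PhantomCohort(samples=samples,
                         split={k: np.asarray(v, dtype=int) for k, v in split.items()})


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, state: dict[str, np.ndarray], meta: dict):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:   # keep the exact filename (no .npz suffixing)
        np.savez(fh, **state)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, default=str))


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"checkpoint not found: {path}")
    with np.load(path) as z:
        state = {k: z[k] for k in z.files}
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return state, meta
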