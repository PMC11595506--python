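"""Study manifests, feature tables, and their on-disk formats.

A *study* is a folder of specimen images with per-region binary masks,
a JSON manifest recording the mask-name registry and the extraction
settings, and (after extraction) a feature table with one row per
(specimen, region).  Manifests are plain JSON and masks are PNG so a
study round-trips bit-exactly through open formats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import MergeError, StudyError
from .image import MaskRegistry

__all__ = [
    "SpecimenRecord",
    "StudyManifest",
    "FeatureTable",
    "export_feature_table",
    "import_feature_table",
    "import_study",
    "concat_tables",
]

KEY_COLUMNS = ["specimen", "region", "label"]


@dataclass
class SpecimenRecord:
    specimen_id: str
    image_path: str
    label: str
    mask_paths: dict[str, str]  # region name -> path
    metadata: dict = field(default_factory=dict)


@dataclass
class StudyManifest:
    study_id: str
    registry: MaskRegistry
    settings: dict
    specimens: list[SpecimenRecord] = field(default_factory=list)
    label_set: tuple[str, ...] = ("high", "low")
    notes: str = ""
    root: Path | None = None

    def validate(self) -> None:
        for rec in self.specimens:
            for region in rec.mask_paths:
                if region not in self.registry:
                    raise StudyError(
                        f"specimen {rec.specimen_id!r}: region {region!r} "
                        "is not in the mask registry"
                    )
            if rec.label not in self.label_set:
                raise StudyError(
                    f"specimen {rec.specimen_id!r}: label {rec.label!r} "
                    f"not in {self.label_set}"
                )

    def resolve(self, path: str) -> Path:
        p = Path(path)
        if p.is_absolute() or self.root is None:
            return p
        return self.root / p

    def to_dict(self) -> dict:
        return {
            "study_id": self.study_id,
            "registry": list(self.registry),
            "settings": self.settings,
            "label_set": list(self.label_set),
            "notes": self.notes,
            "specimens": [
                {
                    "specimen_id": r.specimen_id,
                    "image_path": r.image_path,
                    "label": r.label,
                    "mask_paths": r.mask_paths,
                    "metadata": r.metadata,
                }
                for r in self.specimens
            ],
        }

    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path

    @classmethod
    def load(cls, path) -> "StudyManifest":
        path = Path(path)
        try:
            raw = json.loads(path.read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise StudyError(f"cannot read study manifest {path}") from exc
        manifest = cls(
            study_id=raw["study_id"],
            registry=MaskRegistry(list(raw["registry"])),
            settings=dict(raw["settings"]),
            label_set=tuple(raw.get("label_set", ("high", "low"))),
            notes=raw.get("notes", ""),
            specimens=[
                SpecimenRecord(
                    specimen_id=r["specimen_id"],
                    image_path=r["image_path"],
                    label=r["label"],
                    mask_paths=dict(r["mask_paths"]),
                    metadata=dict(r.get("metadata", {})),
                )
                for r in raw["specimens"]
            ],
            root=path.parent,
        )
        manifest.validate()
        return manifest


@dataclass
class FeatureTable:
    """Samples x features table keyed by (specimen, region) with class labels.

    ``data`` holds the key columns (specimen, region, label) followed by
    the feature columns in canonical order; ``settings`` is the
    extraction-settings fingerprint stamped on the table.
    """

    data: pd.DataFrame
    settings: dict = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in KEY_COLUMNS]

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def region(self, name: str) -> "FeatureTable":
        sub = self.data[self.data["region"] == name].reset_index(drop=True)
        return FeatureTable(sub, dict(self.settings))


def export_feature_table(table: FeatureTable, path, fmt: str | None = None) -> Path:
    """Write a feature table to CSV or XLSX.

    CSV floats are written with 17 significant digits so an
    export -> import round trip reproduces every value exactly.
    """
    if table.n_rows == 0:
        raise ValueError("refusing to export an empty feature table")
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        table.data.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "xlsx":
        table.data.to_excel(path, index=False)
    else:
        raise ValueError(f"unsupported feature-table format {fmt!r}")
    return path


def import_feature_table(path, settings: dict | None = None) -> FeatureTable:
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "xlsx":
        df = pd.read_excel(path)
    else:
        raise ValueError(f"unsupported feature-table format {fmt!r}")
    return FeatureTable(df, dict(settings or {}))


def _settings_diff(a: dict, b: dict) -> list[str]:
    keys = sorted(set(a) | set(b))
    return [k for k in keys if a.get(k) != b.get(k)]


def import_study(path, current: StudyManifest) -> StudyManifest:
    """Merge a completed study into the current session.

    The imported registry names are unioned into the local registry
    (local order first) and specimens are appended.  The merge is refused
    if the extraction settings differ in any key, since feature tables
    extracted under different settings are not comparable.
    """
    incoming = StudyManifest.load(path) if not isinstance(path, StudyManifest) else path
    diff = _settings_diff(current.settings, incoming.settings)
    if diff:
        raise MergeError(
            "cannot merge studies with differing extraction settings: "
            + ", ".join(diff)
        )
    merged = StudyManifest(
        study_id=current.study_id,
        registry=current.registry.merge(incoming.registry),
        settings=dict(current.settings),
        specimens=list(current.specimens) + list(incoming.specimens),
        label_set=current.label_set,
        notes=current.notes,
        root=current.root,
    )
    merged.validate()
    return merged


def concat_tables(a: FeatureTable, b: FeatureTable) -> FeatureTable:
    """Stack two feature tables extracted under identical settings."""
    diff = _settings_diff(a.settings, b.settings)
    if diff:
        raise MergeError(
            "cannot concatenate tables with differing settings: " + ", ".join(diff)
        )
    if a.feature_names != b.feature_names:
        raise MergeError("cannot concatenate tables with differing feature columns")
    return FeatureTable(
        pd.concat([a.data, b.data], ignore_index=True), dict(a.settings)
    )
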