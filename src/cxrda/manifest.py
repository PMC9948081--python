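"""Dataset manifests: CSV files binding image paths to labels, domains and splits.

The CSV dialect is fixed: header ``path,label,domain,split``, UTF-8,
comma-separated, no quoting of plain paths.  Labels, domains and splits come
from closed vocabularies so that a manifest can be validated before any
training starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

LABELS = ("normal", "cardiomegaly")
DOMAINS = ("source", "target")
SPLITS = ("train", "val", "test")

COLUMNS = ["path", "label", "domain", "split"]


class ManifestError(ValueError):
    """Raised for malformed manifests (bad columns, unknown vocabulary, ...)."""


@dataclass
class DatasetManifest:
    """Record table for one dataset.

    ``records`` is a DataFrame with columns ``path, label, domain, split``.
    """

    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=COLUMNS))

    def __post_init__(self):
        self.validate()

    def validate(self, check_paths: bool = False) -> None:
        df = self.records
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ManifestError(f"manifest missing columns: {missing}")
        for col, vocab in (("label", LABELS), ("domain", DOMAINS), ("split", SPLITS)):
            bad = df.index[~df[col].isin(vocab)].tolist()
            if bad:
                raise ManifestError(
                    f"unknown {col} value(s) in rows {bad[:10]}: "
                    f"{sorted(df.loc[bad, col].unique().tolist())}"
                )
        if check_paths:
            absent = [p for p in df["path"] if not Path(p).exists()]
            if absent:
                raise ManifestError(f"missing image files: {absent[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str | None = None, label: str | None = None,
               domain: str | None = None) -> "DatasetManifest":
        df = self.records
        if split is not None:
            df = df[df["split"] == split]
        if label is not None:
            df = df[df["label"] == label]
        if domain is not None:
            df = df[df["domain"] == domain]
        return DatasetManifest(df.reset_index(drop=True))

    def counts(self) -> pd.DataFrame:
        """Per-(label, split) record counts."""
        return self.records.groupby(["label", "split"]).size().unstack(fill_value=0)

    def paths(self) -> list[str]:
        return self.records["path"].tolist()

    def labels(self) -> list[str]:
        return self.records["label"].tolist()


def read_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ManifestError(f"manifest file missing or empty: {path}")
    df = pd.read_csv(path, dtype=str)
    if len(df) == 0:
        raise ManifestError(f"manifest has no records: {path}")
    return DatasetManifest(df)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    manifest.validate()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    manifest.records[COLUMNS].to_csv(path, index=False)
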