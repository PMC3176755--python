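"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["IntensityMatrix", "ExpressionMatrix", "DetectionTable"]


@dataclass
class IntensityMatrix:
    """Raw probe × array intensities with array→(tissue, replicate) metadata.

    Values are positive linear-scale intensities; probe ids are unique.
    """

    values: np.ndarray
    probe_ids: list[str]
    array_ids: list[str]
    array_meta: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.array_ids)):
            raise ValueError("values shape does not match probe/array ids")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("probe ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensities must be finite")
        if np.any(self.values <= 0):
            raise ValueError("intensities must be strictly positive")
        self._probe_index = {p: i for i, p in enumerate(self.probe_ids)}

    def rows(self, probe_ids: list[str]) -> np.ndarray:
        idx = [self._probe_index[p] for p in probe_ids]
        return self.values[idx, :]

    def groups(self) -> dict[str, list[str]]:
        """tissue → array ids, in array order."""
        out: dict[str, list[str]] = {}
        for a in self.array_ids:
            t = self.array_meta.get(a, {}).get("tissue", a)
            out.setdefault(t, []).append(a)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.array_ids)

    def write_tsv(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="probe_id")
        if meta_path is not None:
            rows = [
                {
                    "array_id": a,
                    "tissue": self.array_meta.get(a, {}).get("tissue", ""),
                    "replicate": self.array_meta.get(a, {}).get("replicate", ""),
                }
                for a in self.array_ids
            ]
            pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, meta_path: str | Path | None = None):
        df = pd.read_csv(path, sep="\t", index_col=0)
        meta: dict[str, dict] = {}
        if meta_path is not None:
            m = pd.read_csv(meta_path, sep="\t")
            for _, row in m.iterrows():
                meta[str(row["array_id"])] = {
                    "tissue": str(row["tissue"]),
                    "replicate": row["replicate"],
                }
        return cls(
            values=df.to_numpy(float),
            probe_ids=[str(i) for i in df.index],
            array_ids=[str(c) for c in df.columns],
            array_meta=meta,
        )


@dataclass
class ExpressionMatrix:
    """Probeset × array log2 expression values after summarization."""

    values: np.ndarray
    probeset_ids: list[str]
    array_ids: list[str]
    method: str = "rma"
    array_meta: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probeset_ids), len(self.array_ids)):
            raise ValueError("values shape does not match probeset/array ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        self._ps_index = {p: i for i, p in enumerate(self.probeset_ids)}

    def row(self, probeset_id: str) -> np.ndarray:
        return self.values[self._ps_index[probeset_id], :]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for a in self.array_ids:
            t = self.array_meta.get(a, {}).get("tissue", a)
            out.setdefault(t, []).append(a)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probeset_ids, columns=self.array_ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="probeset_id")


@dataclass
class DetectionTable:
    """Per-probeset detection p-values (per array) and P/M/A calls (per group).

    ``pvalues`` is probesets × arrays in (0, 1]; ``calls`` is a DataFrame of
    single characters in {P, M, A}, probesets × groups.
    """

    pvalues: pd.DataFrame
    calls: pd.DataFrame
    threshold: float = 0.02
    n_repeats: int = 20

    def __post_init__(self) -> None:
        v = self.pvalues.to_numpy(float)
        if np.any((v <= 0) | (v > 1)):
            raise ValueError("detection p-values must lie in (0, 1]")
        bad = set(np.unique(self.calls.to_numpy())) - {"P", "M", "A"}
        if bad:
            raise ValueError(f"invalid call codes: {bad}")

    def present(self, group: str) -> set[str]:
        col = self.calls[group]
        return set(col.index[col == "P"])

    def marginal(self, group: str) -> set[str]:
        col = self.calls[group]
        return set(col.index[col == "M"])

    def write_tsv(self, path) -> None:
        merged = self.pvalues.join(self.calls.add_prefix("call_"))
        merged.to_csv(path, sep="\t", index_label="probeset_id")
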