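"""In-memory containers shared across the pipeline.

Two tabular objects flow through every stage:

* :class:`VocTable` — a long-format table of GC–MS peak areas (one row per
  sample x compound) carrying odor thresholds, retention times and origin
  labels, and, after quantification, internal-standard concentrations.
* :class:`SpectrumSet` — mid-infrared absorbance spectra on a shared
  wavenumber grid (4000–400 cm^-1 by convention, stored descending), with
  sample/replicate bookkeeping and per-sample origin labels.

Both serialize to plain CSV so every intermediate of the pipeline is
inspectable with ordinary tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Required columns of the long-format VOC table.
VOC_COLUMNS = [
    "sample_id",
    "origin",
    "compound_id",
    "cas",
    "rt_min",
    "peak_area",
    "threshold",
]


@dataclass
class VocTable:
    """Long-format volatile-compound table.

    Parameters
    ----------
    data:
        DataFrame with at least :data:`VOC_COLUMNS`; ``true_conc`` (ground
        truth from the generator) and ``conc`` (internal-standard
        quantification result, ug/g) are optional extras.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in VOC_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"VocTable missing columns: {missing}")
        if (self.data["peak_area"] < 0).any():
            raise ValueError("peak_area must be >= 0")
        if (self.data["threshold"] <= 0).any():
            raise ValueError("threshold must be > 0")
        per_sample = self.data.groupby("sample_id")["compound_id"].apply(frozenset)
        if per_sample.nunique() > 1:
            raise ValueError("every sample must carry the same compound set")

    # -- convenience views -------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample_id"]))

    @property
    def compounds(self) -> list[str]:
        return list(dict.fromkeys(self.data["compound_id"]))

    @property
    def origins(self) -> pd.Series:
        """Origin label per sample (index: sample_id)."""
        return self.data.groupby("sample_id", sort=False)["origin"].first()

    def pivot(self, value: str = "conc") -> pd.DataFrame:
        """Wide samples x compounds matrix of ``value``."""
        wide = self.data.pivot(index="sample_id", columns="compound_id", values=value)
        return wide.loc[self.samples, self.compounds]

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "VocTable":
        return cls(pd.read_csv(path))


@dataclass
class SpectrumSet:
    """A stack of absorbance spectra on one wavenumber grid.

    ``absorbance`` is (n_scans, n_points); ``sample_ids`` and ``replicates``
    have one entry per scan; ``origins`` maps sample_id -> class label.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]
    replicates: list[int]
    origins: dict[str, str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be 2-D (n_scans, n_points)")
        if self.absorbance.shape[1] != self.wavenumbers.size:
            raise ValueError("absorbance width must match wavenumber grid")
        if self.absorbance.shape[0] != len(self.sample_ids):
            raise ValueError("one sample_id per scan required")
        if len(self.replicates) != len(self.sample_ids):
            raise ValueError("one replicate index per scan required")
        d = np.diff(self.wavenumbers)
        if not ((d > 0).all() or (d < 0).all()):
            raise ValueError("wavenumber grid must be strictly monotone")
        if not np.isfinite(self.absorbance).all():
            raise ValueError("absorbance contains non-finite values")

    @property
    def n_scans(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.absorbance.shape[1]

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.sample_ids))

    def labels(self) -> np.ndarray:
        """Origin label per scan, aligned with ``absorbance`` rows."""
        return np.array([self.origins[s] for s in self.sample_ids])

    def sample_labels(self) -> np.ndarray:
        """Origin label per unique sample (order of :attr:`samples`)."""
        return np.array([self.origins[s] for s in self.samples])

    def scans_of(self, sample_id: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.sample_ids) if s == sample_id]
        return self.absorbance[idx]

    def with_absorbance(self, absorbance: np.ndarray, **meta) -> "SpectrumSet":
        """Copy with a new absorbance matrix (same scan bookkeeping)."""
        new_meta = {**self.meta, **meta}
        return replace(self, absorbance=np.asarray(absorbance, float), meta=new_meta)

    # -- CSV dialect: first column wavenumber_cm-1, then one col per scan --
    def to_csv(self, path: str | Path) -> None:
        cols = {"wavenumber_cm-1": self.wavenumbers}
        for i, (sid, rep) in enumerate(zip(self.sample_ids, self.replicates)):
            cols[f"{sid}.{rep}"] = self.absorbance[i]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, origins: dict[str, str] | None = None
    ) -> "SpectrumSet":
        df = pd.read_csv(path)
        wn = df.iloc[:, 0].to_numpy()
        sample_ids, replicates = [], []
        for name in df.columns[1:]:
            sid, _, rep = name.rpartition(".")
            sample_ids.append(sid)
            replicates.append(int(rep))
        absorbance = df.iloc[:, 1:].to_numpy().T
        return cls(wn, absorbance, sample_ids, replicates, origins or {})
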