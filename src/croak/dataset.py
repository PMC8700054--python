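"""Coefficient-swept feature datasets: assembly, labelling, splitting, I/O.

The study design turns each source clip into a family of feature rows by
sweeping a filter coefficient — the LPC prediction order P over 22..100 in
steps of 2, or the MFCC pre-emphasis coefficient alpha over 0.22..1.00 in
steps of 0.02 — 40 settings either way.  With 35 species (one clip each)
this yields the canonical 1400 x 10240 feature matrix.  Each row carries the
label string "X_YY": the X-th species at coefficient YY.

Splitting supports two modes.  ``row_random`` reproduces the study's random
70/30 split, stratified per species so every class appears on both sides.
Because all 40 rows of a species derive from one recording, row_random puts
near-duplicate rows in both partitions; ``group_aware`` instead assigns whole
clips to one side and needs >= 2 clips per species.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .audio_io import AudioClip
from .lpc_features import fit_lpc_sweep, spectral_envelope
from .mfcc_features import MFCCConfig, mfcc_feature

LPC_GRID_START, LPC_GRID_STOP, LPC_GRID_STEP = 22, 100, 2
MFCC_GRID_START, MFCC_GRID_STOP, MFCC_GRID_STEP = 0.22, 1.00, 0.02


@dataclass
class FeatureDataset:
    """N x F feature matrix with species / coefficient / clip metadata."""

    matrix: np.ndarray
    species_labels: np.ndarray  # N ints, 1..S
    coeff_values: np.ndarray  # N coefficient settings
    label_strings: list[str]  # N "X_YY" strings
    method: str  # "LPC" | "MFCC"
    group_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.matrix.shape[0]
        if not (len(self.species_labels) == len(self.coeff_values) == len(self.label_strings) == n):
            raise ValueError("metadata lengths must match the matrix row count")
        if not self.group_ids:
            self.group_ids = [""] * n
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_species(self) -> int:
        return int(np.max(self.species_labels))

    def subset(self, idx: np.ndarray) -> "FeatureDataset":
        return FeatureDataset(
            matrix=self.matrix[idx],
            species_labels=self.species_labels[idx],
            coeff_values=self.coeff_values[idx],
            label_strings=[self.label_strings[i] for i in idx],
            method=self.method,
            group_ids=[self.group_ids[i] for i in idx],
        )


def coefficient_grid(method: str) -> list:
    """The swept coefficient settings: 40 LPC orders or 40 alpha values."""
    if method.upper() == "LPC":
        return list(range(LPC_GRID_START, LPC_GRID_STOP + 1, LPC_GRID_STEP))
    if method.upper() == "MFCC":
        n = int(round((MFCC_GRID_STOP - MFCC_GRID_START) / MFCC_GRID_STEP)) + 1
        return [round(MFCC_GRID_START + i * MFCC_GRID_STEP, 2) for i in range(n)]
    raise ValueError(f"unknown feature method {method!r} (expected LPC or MFCC)")


def format_label(species_index: int, coeff, method: str) -> str:
    """Row label "X_YY": species index underscore coefficient as printed."""
    if method.upper() == "LPC":
        return f"{species_index}_{int(coeff)}"
    return f"{species_index}_{coeff:.2f}"


def build_dataset(
    corpus: list[AudioClip],
    method: str,
    grid: list | None = None,
    n_points: int = 10240,
    mfcc_config: MFCCConfig | None = None,
) -> FeatureDataset:
    """One feature row per (clip, coefficient); species-major, coefficient-ascending.

    For LPC the autocorrelation pass is shared across the whole order sweep
    of a clip, so the 40 envelopes cost one FFT plus 40 cheap recursions.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    method = method.upper()
    if grid is None:
        grid = coefficient_grid(method)
    if mfcc_config is None:
        mfcc_config = MFCCConfig(target_len=n_points)
    elif mfcc_config.target_len != n_points:
        raise ValueError("mfcc_config.target_len must equal n_points")

    ordered = sorted(corpus, key=lambda c: (c.species_index, c.clip_id))
    rows, species, coeffs, labels, groups = [], [], [], [], []
    for clip in ordered:
        try:
            if method == "LPC":
                models = fit_lpc_sweep(clip, [int(p) for p in grid])
                feats = [
                    spectral_envelope(m, n_points, clip.rate).values for m in models
                ]
            elif method == "MFCC":
                feats = [mfcc_feature(clip, float(a), mfcc_config) for a in grid]
            else:
                raise ValueError(f"unknown feature method {method!r}")
        except ValueError:
            raise
        except Exception as exc:  # pragma: no cover - defensive context
            raise RuntimeError(
                f"feature extraction failed for clip {clip.clip_id!r} ({method})"
            ) from exc
        for coeff, vec in zip(grid, feats):
            rows.append(vec)
            species.append(clip.species_index)
            coeffs.append(coeff)
            labels.append(format_label(clip.species_index, coeff, method))
            groups.append(clip.clip_id)
    return FeatureDataset(
        matrix=np.asarray(rows, dtype=np.float64),
        species_labels=np.asarray(species, dtype=np.int64),
        coeff_values=np.asarray(coeffs, dtype=np.float64),
        label_strings=labels,
        method=method,
        group_ids=groups,
    )


def split(
    dataset: FeatureDataset,
    test_fraction: float = 0.3,
    seed: int = 0,
    mode: str = "row_random",
) -> tuple[FeatureDataset, FeatureDataset]:
    """Disjoint train/test partition, deterministic in seed.

    row_random: per-species shuffle, round(test_fraction * n_rows_of_species)
    rows go to test — every species appears on both sides.
    group_aware: whole clips (group_ids) assigned to one side per species.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    if mode == "row_random":
        for s in np.unique(dataset.species_labels):
            idx = np.flatnonzero(dataset.species_labels == s)
            n_test = int(round(test_fraction * idx.size))
            n_test = min(max(n_test, 1), idx.size - 1)
            test_idx.extend(rng.permutation(idx)[:n_test])
    elif mode == "group_aware":
        for s in np.unique(dataset.species_labels):
            idx = np.flatnonzero(dataset.species_labels == s)
            groups = sorted({dataset.group_ids[i] for i in idx})
            if len(groups) < 2:
                raise ValueError(
                    f"group_aware split needs >= 2 clips per species; species {s} has {len(groups)}"
                )
            n_test_groups = max(1, int(round(test_fraction * len(groups))))
            n_test_groups = min(n_test_groups, len(groups) - 1)
            chosen = set(
                np.array(groups)[rng.permutation(len(groups))[:n_test_groups]]
            )
            test_idx.extend(i for i in idx if dataset.group_ids[i] in chosen)
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    test_mask = np.zeros(dataset.n_rows, dtype=bool)
    test_mask[np.asarray(test_idx, dtype=np.int64)] = True
    return dataset.subset(np.flatnonzero(~test_mask)), dataset.subset(
        np.flatnonzero(test_mask)
    )


# ---------------------------------------------------------------------------
# Persistence: CSV (interchange) and .npy + JSON sidecar (speed)


def save_csv(dataset: FeatureDataset, path: str | Path) -> None:
    """First column the "X_YY" label, remaining F columns the features."""
    df = pd.DataFrame(dataset.matrix)
    df.insert(0, "label", dataset.label_strings)
    df.to_csv(path, index=False)


def load_csv(path: str | Path, method: str) -> FeatureDataset:
    df = pd.read_csv(path)
    labels = df["label"].astype(str).tolist()
    matrix = df.drop(columns=["label"]).to_numpy(dtype=np.float64)
    species = np.array([int(s.split("_")[0]) for s in labels], dtype=np.int64)
    coeffs = np.array([float(s.split("_")[1]) for s in labels])
    return FeatureDataset(
        matrix=matrix,
        species_labels=species,
        coeff_values=coeffs,
        label_strings=labels,
        method=method.upper(),
    )


def save_binary(dataset: FeatureDataset, path: str | Path) -> None:
    """Write <path>.npy (matrix) plus <path>.json (all metadata)."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), dataset.matrix)
    meta = {
        "method": dataset.method,
        "species_labels": dataset.species_labels.tolist(),
        "coeff_values": dataset.coeff_values.tolist(),
        "label_strings": dataset.label_strings,
        "group_ids": dataset.group_ids,
        "n_features": dataset.n_features,
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_binary(path: str | Path) -> FeatureDataset:
    path = Path(path)
    matrix = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return FeatureDataset(
        matrix=matrix,
        species_labels=np.asarray(meta["species_labels"], dtype=np.int64),
        coeff_values=np.asarray(meta["coeff_values"], dtype=np.float64),
        label_strings=list(meta["label_strings"]),
        method=meta["method"],
        group_ids=list(meta["group_ids"]),
    )


__all__ = [
    "FeatureDataset",
    "coefficient_grid",
    "format_label",
    "build_dataset",
    "split",
    "save_csv",
    "load_csv",
    "save_binary",
    "load_binary",
]
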