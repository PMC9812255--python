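"""Post-hoc analytics: accuracy grids, group-averaged adjacency, screening.

These mirror the standard reporting of a band x connectivity-method sweep:
a results table of test accuracies per (eye state, FC method, band) cell,
element-wise group means of adjacency matrices, and a threshold screen that
lists channel pairs whose average coupling falls below (or above) a cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import STANDARD_BANDS
from .connectivity import FC_METHODS
from .montage import DEFAULT_BIPOLAR_LABELS

BAND_ORDER = ("Delta", "Theta", "Alpha", "Beta", "Gamma", "Full")


@dataclass
class ResultsTable:
    """Test accuracies (%) keyed by (eye_state, fc_method, band)."""

    variant: str = ""
    cells: dict = field(default_factory=dict)

    def add(self, eye_state: str, fc_method: str, band: str,
            accuracy_pct: float) -> None:
        key = (eye_state, fc_method.upper(), band.capitalize())
        if key in self.cells:
            raise ValueError(f"duplicate cell {key}")
        if not 0 <= accuracy_pct <= 100:
            raise ValueError("accuracy must be a percentage in [0, 100]")
        self.cells[key] = float(accuracy_pct)

    def to_frame(self) -> pd.DataFrame:
        """Wide table: rows (eye_state, FC), one column per band; absent
        cells are NaN, never zero."""
        eyes = sorted({k[0] for k in self.cells})
        fcs = [m for m in FC_METHODS
               if any(k[1] == m for k in self.cells)]
        bands = [b for b in BAND_ORDER
                 if any(k[2] == b for k in self.cells)]
        index = pd.MultiIndex.from_product([eyes, fcs],
                                           names=["eye_state", "FC"])
        frame = pd.DataFrame(np.nan, index=index, columns=bands)
        for (eye, fc, band), acc in self.cells.items():
            frame.loc[(eye, fc), band] = acc
        return frame

    def band_means(self) -> pd.Series:
        return self.to_frame().mean(axis=0, skipna=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def accuracy_grid(runs: list[dict], variant: str = "") -> ResultsTable:
    """Assemble a results table from run records (each with ``eye_state``,
    ``fc_method``, ``band`` and ``test_accuracy`` in [0, 1])."""
    table = ResultsTable(variant=variant)
    for run in runs:
        table.add(run["eye_state"], run["fc_method"], run["band"],
                  100.0 * run["test_accuracy"])
    return table


@dataclass
class AveragedAdjacency:
    """Element-wise mean adjacency over a mini-epoch selection."""

    W: np.ndarray
    count: int
    group: str = ""
    eye_state: str = ""
    method: str = ""
    band: str = ""
    channel_labels: list[str] = field(default_factory=list)


def average_adjacency(W_stack: np.ndarray, minis=None, *,
                      group: str | None = None, eye_state: str | None = None,
                      method: str = "", band: str = "",
                      channel_labels: list[str] | None = None
                      ) -> AveragedAdjacency:
    """Mean adjacency over (optionally filtered) mini-epochs.

    ``W_stack`` is [N, n, n]; when ``minis`` metadata is given, ``group`` /
    ``eye_state`` select the matching subset.
    """
    W_stack = np.asarray(W_stack, dtype=float)
    mask = np.ones(W_stack.shape[0], dtype=bool)
    if minis is not None:
        if group is not None:
            mask &= np.array([m.group == group for m in minis])
        if eye_state is not None:
            mask &= np.array([m.eye_state == eye_state for m in minis])
    if not mask.any():
        raise ValueError("empty selection for adjacency averaging")
    n = W_stack.shape[-1]
    labels = channel_labels or (DEFAULT_BIPOLAR_LABELS if n == 23 else
                                [f"ch{i:02d}" for i in range(n)])
    return AveragedAdjacency(W=W_stack[mask].mean(axis=0),
                             count=int(mask.sum()), group=group or "",
                             eye_state=eye_state or "", method=method,
                             band=band, channel_labels=labels)


def threshold_screen(avg: AveragedAdjacency, threshold: float,
                     mode: str = "below") -> list[tuple[str, str]]:
    """Channel pairs (i < j) whose mean coupling is below / at-or-above the
    threshold.  An empty list is a valid outcome."""
    if mode not in ("below", "above"):
        raise ValueError("mode must be 'below' or 'above'")
    n = avg.W.shape[0]
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            v = avg.W[i, j]
            if (mode == "below" and v < threshold) or \
                    (mode == "above" and v >= threshold):
                out.append((avg.channel_labels[i], avg.channel_labels[j]))
    return out


def group_difference(avg_a: AveragedAdjacency,
                     avg_b: AveragedAdjacency) -> np.ndarray:
    """Element-wise difference of two averaged adjacencies (a - b)."""
    return avg_a.W - avg_b.W


def top_pairs(diff: np.ndarray, k: int = 10) -> list[tuple[int, int]]:
    """The k channel pairs (i < j) with largest |difference|."""
    n = diff.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    order = np.argsort(np.abs(diff[iu, ju]))[::-1][:k]
    return [(int(iu[o]), int(ju[o])) for o in order]


def plot_adjacency(avg: AveragedAdjacency, ax=None, **imshow_kwargs):
    """Heatmap of an averaged adjacency in canonical derivation order."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(avg.W, vmin=0, **imshow_kwargs)
    ax.set_xticks(range(len(avg.channel_labels)))
    ax.set_yticks(range(len(avg.channel_labels)))
    ax.set_xticklabels(avg.channel_labels, rotation=90, fontsize=6)
    ax.set_yticklabels(avg.channel_labels, fontsize=6)
    title = " ".join(filter(None, [avg.group, avg.eye_state, avg.method,
                                   avg.band, f"(n={avg.count})"]))
    ax.set_title(title, fontsize=9)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax
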