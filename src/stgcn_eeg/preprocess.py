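"""Filtering, resampling, segmentation and dataset splits.

The pipeline turns raw recordings into labelled 23-channel x 25-sample
mini-epochs: band-pass filter at the original rate (zero-phase Butterworth,
which also anti-aliases since every band tops out at 48 Hz), decimate to the
100 Hz working rate, then cut non-overlapping 25-sample windows.  A 12-s
epoch at 100 Hz yields exactly 48 windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import scipy.signal

from .bands import BandSpec
from .recording import Recording

#: Canonical mini-epoch geometry: channels (graph nodes) x samples.
N_NODES = 23
WINDOW_LEN = 25
#: Working sampling rate after decimation, Hz.
WORKING_FS = 100.0

#: Class label convention: the patient-like group codes as 1.
GROUP_LABELS = {"AD-like": 1, "HC-like": 0}


@dataclass
class MiniEpoch:
    """One classification sample: a short multichannel window.

    ``X`` has shape (n_channels, window_len); canonical geometry is 23 x 25
    (0.25 s at 100 Hz).  ``start`` is the 0-based sample offset of the
    half-open window [start, start + window_len) in the source epoch.
    """

    X: np.ndarray
    band: BandSpec | None = None
    label: int = 0
    group: str = ""
    eye_state: str = ""
    subject_id: str = ""
    source_epoch_index: int = 0
    start: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("mini-epoch X must be 2-D")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("mini-epoch contains non-finite values")

    @property
    def epoch_key(self) -> tuple:
        """Identity of the source 12-s epoch (the stratification unit)."""
        return (self.group, self.subject_id, self.eye_state,
                self.source_epoch_index)

    def validate_canonical(self) -> None:
        if self.X.shape != (N_NODES, WINDOW_LEN):
            raise ValueError(
                f"expected {N_NODES}x{WINDOW_LEN} mini-epoch, got {self.X.shape}"
            )


@dataclass
class DatasetSplit:
    """Train/val vs test indices with a k-fold partition of train/val."""

    train_val_ids: list[int]
    test_ids: list[int]
    cv_folds: list[list[int]]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_val_ids) & set(self.test_ids):
            raise ValueError("train/val and test indices overlap")
        covered = sorted(i for fold in self.cv_folds for i in fold)
        if covered != sorted(self.train_val_ids):
            raise ValueError("folds must partition train/val exactly")
        sizes = [len(f) for f in self.cv_folds]
        if sizes and max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes may differ by at most 1")

    def fold_split(self, fold: int) -> tuple[list[int], list[int]]:
        """(train_ids, val_ids) for one cross-validation fold."""
        val = list(self.cv_folds[fold])
        val_set = set(val)
        train = [i for i in self.train_val_ids if i not in val_set]
        return train, val


def bandpass_filter(rec: Recording, band: BandSpec, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel.

    The filter is applied forward-backward (``sosfiltfilt``), preserving
    phase so that downstream phase-synchronisation measures are unbiased.
    """
    if order < 1:
        raise ValueError("filter order must be >= 1")
    nyq = rec.fs / 2
    if not (0 <= band.low_hz < band.high_hz):
        raise ValueError(f"bad band {band}")
    if band.high_hz >= nyq:
        raise ValueError(
            f"band {band.name} ({band.low_hz}-{band.high_hz} Hz) exceeds "
            f"Nyquist {nyq} Hz"
        )
    if band.low_hz > 0:
        sos = scipy.signal.butter(order, [band.low_hz, band.high_hz],
                                  btype="bandpass", fs=rec.fs, output="sos")
    else:
        sos = scipy.signal.butter(order, band.high_hz, btype="lowpass",
                                  fs=rec.fs, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, rec.samples, axis=1)
    out = rec.with_samples(filtered)
    out.meta = {**rec.meta, "band": band.name}
    return out


def resample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased polyphase resampling down to ``target_fs``.

    Output length is ``floor(n_samples * target_fs / fs)``.
    """
    if target_fs > rec.fs:
        raise ValueError(f"target_fs {target_fs} exceeds recording fs {rec.fs}")
    if target_fs == rec.fs:
        return rec.with_samples(rec.samples.copy())
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    out = scipy.signal.resample_poly(rec.samples, ratio.numerator,
                                     ratio.denominator, axis=1)
    n_out = int(np.floor(rec.n_samples * target_fs / rec.fs))
    return rec.with_samples(out[:, :n_out], fs=target_fs)


def segment(rec: Recording, window: int = WINDOW_LEN,
            overlap: int = 0) -> list[MiniEpoch]:
    """Cut a recording into complete windows; the incomplete tail is dropped.

    With ``overlap = 0`` the count is ``floor(n_samples / window)``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not (0 <= overlap < window):
        raise ValueError("overlap must satisfy 0 <= overlap < window")
    step = window - overlap
    n = rec.n_samples
    if n < window:
        return []
    count = (n - overlap) // step
    band_name = rec.meta.get("band")
    band = None
    if band_name is not None:
        from .bands import STANDARD_BANDS

        band = STANDARD_BANDS.get(band_name)
    label = GROUP_LABELS.get(rec.group, 0)
    out = []
    for w in range(count):
        start = w * step
        out.append(MiniEpoch(
            X=rec.samples[:, start:start + window].copy(),
            band=band,
            label=label,
            group=rec.group,
            eye_state=rec.eye_state,
            subject_id=rec.subject_id,
            source_epoch_index=rec.epoch_index,
            start=start,
        ))
    return out


def split_dataset(dataset: list[MiniEpoch], train_frac: float = 2 / 3,
                  k: int = 10, seed: int = 0,
                  mode: str = "mini-epoch") -> DatasetSplit:
    """Reproducible train-val/test split with a k-fold partition.

    ``mini-epoch`` mode draws ``train_frac`` of the windows *within each
    source 12-s epoch* (so every epoch contributes both train and test
    windows); ``subject-hand-out`` mode assigns whole subjects to train or
    test, with ``train_frac`` of the subjects of each group in train.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)

    if mode == "mini-epoch":
        strata: dict[tuple, list[int]] = {}
        for i, me in enumerate(dataset):
            strata.setdefault(me.epoch_key, []).append(i)
        train_val: list[int] = []
        test: list[int] = []
        for key in sorted(strata):
            ids = np.array(strata[key])
            n_train = int(round(train_frac * len(ids)))
            perm = rng.permutation(len(ids))
            train_val.extend(ids[perm[:n_train]].tolist())
            test.extend(ids[perm[n_train:]].tolist())
    elif mode == "subject-hand-out":
        by_group: dict[str, list[str]] = {}
        for me in dataset:
            subs = by_group.setdefault(me.group, [])
            if me.subject_id not in subs:
                subs.append(me.subject_id)
        train_subjects: set[tuple[str, str]] = set()
        for group in sorted(by_group):
            subs = sorted(by_group[group])
            n_train = int(round(train_frac * len(subs)))
            chosen = rng.permutation(len(subs))[:n_train]
            train_subjects.update((group, subs[c]) for c in chosen)
        train_val = [i for i, me in enumerate(dataset)
                     if (me.group, me.subject_id) in train_subjects]
        test = [i for i, me in enumerate(dataset)
                if (me.group, me.subject_id) not in train_subjects]
    else:
        raise ValueError(f"unknown split mode {mode!r}")

    if k > len(train_val):
        raise ValueError(f"k={k} folds exceed train/val size {len(train_val)}")
    order = rng.permutation(len(train_val))
    folds: list[list[int]] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(train_val[idx])
    return DatasetSplit(train_val_ids=train_val, test_ids=test,
                        cv_folds=folds, seed=seed)
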