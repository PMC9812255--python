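"""Bipolar derivations.

Differencing neighbouring electrode potentials removes the common reference
and attenuates volume-conducted zero-lag components.  The default table is
the fixed 23-pair longitudinal/transverse set used throughout the package;
its order defines the channel axis of every adjacency matrix.
"""

from __future__ import annotations

import numpy as np

from .recording import Recording

#: The 23 (anode, cathode) bipolar derivations, in canonical order.
DEFAULT_BIPOLAR_PAIRS: list[tuple[str, str]] = [
    ("F8", "F4"), ("F7", "F3"), ("F4", "C4"), ("F3", "C3"), ("F4", "FZ"),
    ("FZ", "CZ"), ("F3", "FZ"), ("T4", "C4"), ("T3", "C3"), ("C4", "CZ"),
    ("C3", "CZ"), ("CZ", "PZ"), ("C4", "P4"), ("C3", "P3"), ("T4", "T6"),
    ("T3", "T5"), ("P4", "PZ"), ("P3", "PZ"), ("T6", "O2"), ("T5", "O1"),
    ("P4", "O2"), ("P3", "O1"), ("O1", "O2"),
]

#: Labels of the 23 derived channels ("A-B"), in canonical order.
DEFAULT_BIPOLAR_LABELS: list[str] = [f"{a}-{b}" for a, b in DEFAULT_BIPOLAR_PAIRS]

#: Electrode names the default table draws on (10-20 subset).
ELECTRODES_1020 = sorted({e for pair in DEFAULT_BIPOLAR_PAIRS for e in pair})


class MontageError(KeyError):
    """A derivation references an electrode absent from the recording."""


def apply_bipolar_montage(
    rec: Recording,
    pairs: list[tuple[str, str]] | None = None,
) -> Recording:
    """Form bipolar channels ``anode - cathode``.

    With ``pairs=None`` the default 23-derivation table is used, and the
    output channel order is its canonical order.  Electrode-label matching is
    case-insensitive.
    """
    if pairs is None:
        pairs = DEFAULT_BIPOLAR_PAIRS
    index = {lab.upper(): i for i, lab in enumerate(rec.channel_labels)}
    rows = []
    for anode, cathode in pairs:
        try:
            ia, ic = index[anode.upper()], index[cathode.upper()]
        except KeyError as exc:
            raise MontageError(
                f"electrode {exc.args[0]} not in recording "
                f"(channels: {rec.channel_labels})"
            ) from None
        rows.append(rec.samples[ia] - rec.samples[ic])
    labels = [f"{a}-{b}" for a, b in pairs]
    return rec.with_samples(np.stack(rows), channel_labels=labels)
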