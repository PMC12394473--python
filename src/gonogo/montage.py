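"""The 19-channel 10-20 montage used throughout the pipeline.

Channel order follows the conventional listing for a 19-electrode
clinical recording (Fp1 .. O2) with a linked-ears reference.
"""

from __future__ import annotations

import numpy as np

#: The 19 scalp electrodes of the 10-20 system, in recording order.
CHANNELS_10_20: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "T4", "T5", "T6",
    "C3", "Cz", "C4",
    "P3", "Pz", "P4",
    "O1", "O2",
)

N_CHANNELS = len(CHANNELS_10_20)

#: Default sampling rate of the acquisition system, Hz.
SAMPLING_RATE_HZ = 250.0

#: Default reference label.
REFERENCE = "linked ears"

#: Default midline adjacency for cluster formation: Fz and Cz are neighbours.
DEFAULT_ADJACENCY: tuple[tuple[str, str], ...] = (("Fz", "Cz"),)


def channel_index(name: str, channels: tuple[str, ...] = CHANNELS_10_20) -> int:
    """Index of ``name`` in ``channels``, with a helpful error."""
    try:
        return channels.index(name)
    except ValueError:
        raise KeyError(
            f"unknown channel {name!r}; valid channels: {', '.join(channels)}"
        ) from None


def topography_from(gains: dict[str, float],
                    channels: tuple[str, ...] = CHANNELS_10_20) -> np.ndarray:
    """Build a per-channel gain vector from a ``{channel: gain}`` mapping.

    Channels absent from ``gains`` get zero gain.  Unknown channel names
    raise ``KeyError`` listing the valid names.
    """
    topo = np.zeros(len(channels))
    for name, g in gains.items():
        topo[channel_index(name, channels)] = float(g)
    return topo


def adjacency_matrix(pairs=DEFAULT_ADJACENCY,
                     channels: tuple[str, ...] = ("Fz", "Cz")) -> np.ndarray:
    """Boolean channel x channel adjacency matrix from neighbour pairs.

    Pairs whose members are not both in ``channels`` are ignored, so the
    default montage-wide pair list can be reused for channel subsets.
    """
    n = len(channels)
    adj = np.zeros((n, n), dtype=bool)
    for a, b in pairs:
        if a in channels and b in channels:
            i, j = channels.index(a), channels.index(b)
            adj[i, j] = adj[j, i] = True
    return adj
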