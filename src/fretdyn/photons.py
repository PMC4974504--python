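"""Time-tagged two-channel photon streams and their on-disk formats.

A photon stream is the primary record of a confocal FCS/FCCS measurement:
for every detected photon, an arrival time (seconds from the start of the
acquisition) and a detection channel (donor or acceptor).  Streams are
written either as HDF5 (datasets ``/photon_times`` float64 seconds and
``/channel`` uint8, attributes carrying resolution, seed and a config echo)
or as a two-column CSV ``time_s, channel``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DONOR",
    "ACCEPTOR",
    "PhotonStream",
    "write_photons_hdf5",
    "read_photons_hdf5",
    "write_photons_csv",
    "read_photons_csv",
]

DONOR = 0
ACCEPTOR = 1
_CHANNEL_NAMES = {DONOR: "donor", ACCEPTOR: "acceptor"}


@dataclass
class PhotonStream:
    """Channel-tagged photon arrival times.

    Attributes
    ----------
    times : ndarray of float64
        Arrival times in seconds, monotone non-decreasing, within
        ``[0, duration]``.
    channels : ndarray of uint8
        Per-photon channel label, 0 = donor, 1 = acceptor.
    duration : float
        Acquisition length in seconds.
    resolution : float
        Underlying timing resolution in seconds (simulation step or hardware
        clock period).
    metadata : dict
        Configuration echo, seed, provenance.
    """

    times: np.ndarray
    channels: np.ndarray
    duration: float
    resolution: float = 1e-6
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.channels = np.asarray(self.channels, dtype=np.uint8)
        if self.times.shape != self.channels.shape:
            raise ValueError("times and channels must have equal length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("photon times must be sorted")
        if self.times.size and (self.times[0] < 0 or self.times[-1] > self.duration):
            raise ValueError("photon times must lie in [0, duration]")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        bad = set(np.unique(self.channels)) - set(_CHANNEL_NAMES)
        if bad:
            raise ValueError(f"unknown channel labels {sorted(bad)}")

    def __len__(self) -> int:
        return self.times.size

    def channel_times(self, channel: int) -> np.ndarray:
        """Arrival times of one channel (0 = donor, 1 = acceptor)."""
        return self.times[self.channels == channel]

    def count_rate(self, channel: int | None = None) -> float:
        """Mean detected count rate (photons/s), total or per channel."""
        n = len(self) if channel is None else int((self.channels == channel).sum())
        return n / self.duration


def write_photons_hdf5(stream: PhotonStream, path) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("photon_times", data=stream.times, dtype="f8")
        h5.create_dataset("channel", data=stream.channels, dtype="u1")
        h5.attrs["duration_s"] = stream.duration
        h5.attrs["resolution_s"] = stream.resolution
        h5.attrs["config_json"] = json.dumps(stream.metadata, sort_keys=True)


def read_photons_hdf5(path) -> PhotonStream:
    import h5py

    with h5py.File(path, "r") as h5:
        meta = json.loads(h5.attrs.get("config_json", "{}"))
        return PhotonStream(
            times=h5["photon_times"][:],
            channels=h5["channel"][:],
            duration=float(h5.attrs["duration_s"]),
            resolution=float(h5.attrs.get("resolution_s", 1e-6)),
            metadata=meta,
        )


def write_photons_csv(stream: PhotonStream, path) -> None:
    import pandas as pd

    pd.DataFrame({"time_s": stream.times, "channel": stream.channels}).to_csv(
        path, index=False
    )


def read_photons_csv(path, duration: float | None = None,
                     resolution: float = 1e-6) -> PhotonStream:
    import pandas as pd

    df = pd.read_csv(path)
    times = df["time_s"].to_numpy(dtype=np.float64)
    if duration is None:
        duration = float(times[-1]) if times.size else 1.0
    return PhotonStream(
        times=times,
        channels=df["channel"].to_numpy(dtype=np.uint8),
        duration=duration,
        resolution=resolution,
    )
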