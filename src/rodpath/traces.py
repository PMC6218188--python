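"""Trace containers and the keyed trace store.

A :class:`Trace` is a uniformly sampled time series (photocurrent,
membrane voltage, excitatory current or firing rate) with the metadata
needed to analyse it: cell type, species, pharmacological condition,
the stimulus that evoked it and the seed that generated it.  A
:class:`TraceStore` is an insertion-ordered, keyed collection of traces
with protocol provenance, persisted to HDF5 (one group per trace) or
exported to CSV summary tables.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np

__all__ = ["StimulusSpec", "Trace", "TraceStore"]

#: units accepted on a trace; spikes_s is a (PSTH) firing rate
VALID_UNITS = ("pA", "mV", "spikes_s")

VALID_STIM_KINDS = ("flash", "step", "sinusoid")
VALID_LEDS = ("rod_preferring", "mid", "cone_preferring")


@dataclasses.dataclass(frozen=True)
class StimulusSpec:
    """Full-field stimulus description.

    Parameters
    ----------
    kind:
        ``"flash"`` (brief increment at t=0), ``"step"`` (background step
        held for the stimulus epoch) or ``"sinusoid"`` (contrast
        modulation of the background).
    background:
        Mean photoisomerization rate in R*/rod/s.
    contrast:
        Weber contrast of the stimulus; 6.0 means a 600% contrast flash.
        Flash strength then scales with the background so that contrast
        is fixed across light levels.
    duration_s:
        Flash duration (seconds); the canonical probe flash is 10 ms.
    strength_rstar:
        Optional absolute flash strength in R*/rod.  When given it
        overrides the contrast-scaled strength — used e.g. for the
        saturating reference flash delivered from darkness.
    frequency_hz:
        Sinusoid frequency; required for ``kind="sinusoid"``.
    led:
        Which LED class delivered the stimulus; controls the relative
        rod- and cone-pathway drive in the generative model.
    pre_s / stim_s / tail_s / dt_s:
        Trace timing: pre-stimulus epoch, stimulus epoch, post-stimulus
        tail, and sample interval.  t = 0 is stimulus onset.
    """

    kind: str
    background: float
    pre_background: float = 0.0
    contrast: float = 0.0
    duration_s: float = 0.010
    strength_rstar: float | None = None
    frequency_hz: float | None = None
    led: str = "rod_preferring"
    pre_s: float = 0.5
    stim_s: float = 1.0
    tail_s: float = 1.0
    dt_s: float = 1e-3

    def __post_init__(self) -> None:
        if self.kind not in VALID_STIM_KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}; expected one of {VALID_STIM_KINDS}")
        if self.led not in VALID_LEDS:
            raise ValueError(f"unknown led {self.led!r}; expected one of {VALID_LEDS}")
        if self.background < 0 or self.pre_background < 0:
            raise ValueError("background must be >= 0 (R*/rod/s)")
        if self.contrast < -1:
            raise ValueError("contrast must be >= -1")
        if self.duration_s <= 0 or self.dt_s <= 0:
            raise ValueError("duration_s and dt_s must be positive")
        if self.kind == "sinusoid" and (self.frequency_hz is None or self.frequency_hz <= 0):
            raise ValueError("sinusoid stimulus requires frequency_hz > 0")

    @property
    def flash_strength(self) -> float:
        """Total R*/rod delivered during the flash window (background plus increment)."""
        if self.strength_rstar is not None:
            return float(self.strength_rstar)
        return (1.0 + self.contrast) * self.background * self.duration_s

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        return cls(**d)


@dataclasses.dataclass
class Trace:
    """A uniformly sampled time series with experiment metadata.

    ``meta`` carries at least ``cell_type``, ``species``, ``condition``
    and ``seed``; ``stimulus`` is the :class:`StimulusSpec` that evoked
    the trace.
    """

    t0: float
    dt: float
    values: np.ndarray
    units: str
    stimulus: StimulusSpec | None = None
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.units not in VALID_UNITS:
            raise ValueError(f"units must be one of {VALID_UNITS}, got {self.units!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds (t = 0 at stimulus onset by convention)."""
        return self.t0 + self.dt * np.arange(self.n)

    def window(self, t_start: float, t_stop: float) -> "Trace":
        """Crop to ``t_start <= t < t_stop`` (seconds)."""
        t = self.time
        mask = (t >= t_start) & (t < t_stop)
        if not mask.any():
            raise ValueError("window does not overlap the trace extent")
        i0 = int(np.argmax(mask))
        return Trace(t0=t[i0], dt=self.dt, values=self.values[mask].copy(),
                     units=self.units, stimulus=self.stimulus, meta=dict(self.meta))

    def baseline(self, fraction: float = 0.2) -> float:
        """Mean of the final ``fraction`` of the pre-stimulus epoch (t < 0).

        Falls back to the first sample when the trace starts at or after
        stimulus onset.
        """
        t = self.time
        pre = self.values[t < 0]
        if len(pre) == 0:
            return float(self.values[0])
        k = max(1, int(round(fraction * len(pre))))
        return float(pre[-k:].mean())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trace):
            return NotImplemented
        return (
            self.t0 == other.t0
            and self.dt == other.dt
            and self.units == other.units
            and np.array_equal(self.values, other.values)
            and self.stimulus == other.stimulus
            and self.meta == other.meta
        )


class TraceStore:
    """Keyed, ordered collection of traces with protocol provenance."""

    def __init__(self, protocol: dict | None = None) -> None:
        self._traces: dict[str, Trace] = {}
        self.protocol: dict = dict(protocol or {})

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._traces)

    def __iter__(self) -> Iterator[Trace]:
        return iter(self._traces.values())

    def __getitem__(self, key: str) -> Trace:
        return self._traces[key]

    def keys(self):
        return self._traces.keys()

    def add(self, trace: Trace, key: str | None = None) -> str:
        if key is None:
            key = f"trace{len(self._traces):05d}"
        if key in self._traces:
            raise KeyError(f"duplicate trace key {key!r}")
        self._traces[key] = trace
        return key

    # -- querying -----------------------------------------------------------
    def select(self, **filters) -> list[Trace]:
        """Return traces whose metadata/stimulus fields match ``filters``.

        Filter keys are looked up first in ``trace.meta`` and then on the
        stimulus (e.g. ``background=10``, ``cell_type="AII"``). Floats
        are compared with a relative tolerance.
        """
        out = []
        for tr in self:
            ok = True
            for k, want in filters.items():
                if k in tr.meta:
                    have = tr.meta[k]
                elif tr.stimulus is not None and hasattr(tr.stimulus, k):
                    have = getattr(tr.stimulus, k)
                else:
                    ok = False
                    break
                if isinstance(want, float) or isinstance(have, float):
                    try:
                        ok = bool(np.isclose(float(have), float(want), rtol=1e-9, atol=0.0))
                    except (TypeError, ValueError):
                        ok = False
                else:
                    ok = have == want
                if not ok:
                    break
            if ok:
                out.append(tr)
        return out

    def backgrounds(self, **filters) -> np.ndarray:
        """Sorted unique backgrounds among selected traces."""
        bgs = {tr.stimulus.background for tr in self.select(**filters) if tr.stimulus is not None}
        return np.array(sorted(bgs))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraceStore):
            return NotImplemented
        return (
            sorted(self.keys()) == sorted(other.keys())
            and all(self[k] == other[k] for k in self.keys())
            and self.protocol == other.protocol
        )

    # -- persistence ----------------------------------------------------------
    def to_hdf5(self, path: str | Path) -> None:
        """Write the store to HDF5: ``/traces/<key>`` datasets plus a
        ``/protocol`` group holding the verbatim protocol as JSON."""
        with h5py.File(path, "w") as f:
            grp = f.create_group("traces")
            for key, tr in self._traces.items():
                g = grp.create_group(key)
                d = g.create_dataset("values", data=tr.values, track_times=False)
                d.attrs["units"] = tr.units
                g.attrs["t0"] = tr.t0
                g.attrs["dt"] = tr.dt
                g.attrs["units"] = tr.units
                for mk, mv in tr.meta.items():
                    g.attrs[mk] = mv if mv is not None else "null"
                if tr.stimulus is not None:
                    g.attrs["stimulus_json"] = json.dumps(tr.stimulus.to_dict())
            p = f.create_group("protocol")
            p.attrs["json"] = json.dumps(self.protocol, sort_keys=True)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "TraceStore":
        store = cls()
        with h5py.File(path, "r") as f:
            store.protocol = json.loads(f["protocol"].attrs["json"])
            keys: list[str] = []
            f["traces"].visititems(
                lambda name, obj: keys.append(name.rsplit("/values", 1)[0])
                if isinstance(obj, h5py.Dataset) and name.endswith("values") else None)
            for key in sorted(keys):
                g = f["traces"][key]
                stim = None
                meta = {}
                for ak, av in g.attrs.items():
                    if ak in ("t0", "dt", "units"):
                        continue
                    if ak == "stimulus_json":
                        stim = StimulusSpec.from_dict(json.loads(av))
                    else:
                        meta[ak] = None if (isinstance(av, str) and av == "null") else _denumpy(av)
                store.add(
                    Trace(t0=float(g.attrs["t0"]), dt=float(g.attrs["dt"]),
                          values=g["values"][...], units=str(g.attrs["units"]),
                          stimulus=stim, meta=meta),
                    key=key,
                )
        return store

    def summary_frame(self):
        """One row of metadata per trace (no sample values)."""
        import pandas as pd

        rows = []
        for key, tr in self._traces.items():
            row = {"key": key, "t0": tr.t0, "dt": tr.dt, "units": tr.units, "n": tr.n}
            row.update(tr.meta)
            if tr.stimulus is not None:
                row.update({f"stim_{k}": v for k, v in tr.stimulus.to_dict().items()})
            rows.append(row)
        return pd.DataFrame(rows)


def _denumpy(v):
    """Convert h5py attribute scalars back to plain python types."""
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.generic):
        return v.item()
    return v
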