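"""HDF5 serialization of simulation traces.

One group per snapshot (``snap_000``, ``snap_001``, ...) with datasets
``vertices``, ``faces``, ``u``, ``v``, ``curvature`` and a ``time``
attribute; the per-iteration area series lives at the file root.
"""

from __future__ import annotations

import h5py
import numpy as np

from .mesh_core import TriangleMesh
from .deformation import SimulationTrace, Snapshot

__all__ = ["save_trace", "load_trace"]


def save_trace(trace: SimulationTrace, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("area_times", data=np.asarray(trace.area_times))
        f.create_dataset("areas", data=np.asarray(trace.areas))
        for i, snap in enumerate(trace.snapshots):
            g = f.create_group(f"snap_{i:03d}")
            g.attrs["time"] = snap.time
            g.create_dataset("vertices", data=snap.mesh.vertices)
            g.create_dataset("faces", data=snap.mesh.faces)
            g.create_dataset("u", data=snap.u)
            g.create_dataset("v", data=snap.v)
            g.create_dataset("curvature", data=snap.curvature)


def load_trace(path) -> SimulationTrace:
    trace = SimulationTrace()
    with h5py.File(path, "r") as f:
        trace.area_times = list(np.asarray(f["area_times"]))
        trace.areas = list(np.asarray(f["areas"]))
        names = sorted(k for k in f.keys() if k.startswith("snap_"))
        for name in names:
            g = f[name]
            trace.snapshots.append(
                Snapshot(
                    time=float(g.attrs["time"]),
                    mesh=TriangleMesh(np.asarray(g["vertices"]), np.asarray(g["faces"])),
                    u=np.asarray(g["u"]),
                    v=np.asarray(g["v"]),
                    curvature=np.asarray(g["curvature"]),
                )
            )
    return trace
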