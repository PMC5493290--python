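"""Snapshot, event-log and trajectory I/O (plain delimited text).

A snapshot is two tab-separated tables: a particle table (id, flag, type,
x, y, theta, A0, age) and a boundary-connectivity table (id, left, right)
listing each boundary ghost's two neighbours on its loop, plus per-loop
``fixed`` flags.  The mesh itself is never serialised; it is rebuilt from
the particle positions.  Floats are written with full round-trip precision
so that write -> read -> write is byte-identical and restarts are
bit-reproducible.
"""

from __future__ import annotations

import io
import json
from pathlib import Path

import numpy as np

from .tissue import Tissue, FLAG_INTERIOR

__all__ = [
    "snapshot_text",
    "write_snapshot",
    "read_snapshot",
    "write_events",
    "read_events",
    "interior_table",
    "aligned_positions",
]

_FMT = "%.17g"


def snapshot_text(tissue: Tissue) -> str:
    """Serialise a tissue to the snapshot text format."""
    buf = io.StringIO()
    buf.write("# particles\n")
    buf.write("id\tflag\ttype\tx\ty\ttheta\tA0\tage\n")
    for k in range(tissue.n_sites):
        buf.write(
            "\t".join(
                [
                    str(int(tissue.ids[k])),
                    str(int(tissue.flags[k])),
                    str(int(tissue.types[k])),
                    _FMT % tissue.pos[k, 0],
                    _FMT % tissue.pos[k, 1],
                    _FMT % tissue.theta[k],
                    _FMT % tissue.A0[k],
                    _FMT % tissue.age[k],
                ]
            )
            + "\n"
        )
    buf.write("# boundary\n")
    buf.write("id\tleft\tright\tloop\tfixed\n")
    for li, loop in enumerate(tissue.loops):
        ids = tissue.ids[loop]
        left = np.roll(ids, 1)
        right = np.roll(ids, -1)
        fx = int(tissue.loop_fixed[li])
        for a, l, r in zip(ids, left, right):
            buf.write(f"{int(a)}\t{int(l)}\t{int(r)}\t{li}\t{fx}\n")
    buf.write(f"# n_types\t{tissue.n_types}\n")
    return buf.getvalue()


def write_snapshot(tissue: Tissue, path: str | Path) -> None:
    Path(path).write_text(snapshot_text(tissue))


def read_snapshot(path: str | Path) -> Tissue:
    """Rebuild a tissue from a snapshot file (mesh is reconstructed lazily)."""
    lines = Path(path).read_text().splitlines()
    section = None
    particles = []
    bnd_rows = []
    n_types = 1
    for ln in lines:
        if ln.startswith("# particles"):
            section = "p"
            continue
        if ln.startswith("# boundary"):
            section = "b"
            continue
        if ln.startswith("# n_types"):
            n_types = int(ln.split("\t")[1])
            continue
        if ln.startswith("id\t") or not ln.strip():
            continue
        parts = ln.split("\t")
        if section == "p":
            particles.append(parts)
        elif section == "b":
            bnd_rows.append(parts)
    ids = np.array([int(p[0]) for p in particles], dtype=np.int64)
    flags = np.array([int(p[1]) for p in particles], dtype=np.int8)
    types = np.array([int(p[2]) for p in particles], dtype=np.int64)
    pos = np.array([[float(p[3]), float(p[4])] for p in particles])
    theta = np.array([float(p[5]) for p in particles])
    A0 = np.array([float(p[6]) for p in particles])
    age = np.array([float(p[7]) for p in particles])
    idx_of = {int(i): k for k, i in enumerate(ids)}
    # reconstruct loops by walking the right-neighbour maps per loop label
    loops: dict[int, list[int]] = {}
    right_of: dict[int, int] = {}
    fixed: dict[int, bool] = {}
    first: dict[int, int] = {}
    for a, l, r, li, fx in bnd_rows:
        li = int(li)
        right_of[int(a)] = int(r)
        fixed[li] = bool(int(fx))
        first.setdefault(li, int(a))
    for li, start in first.items():
        walk = [start]
        cur = right_of[start]
        while cur != start:
            walk.append(cur)
            cur = right_of[cur]
        loops[li] = [idx_of[i] for i in walk]
    loop_list = [np.asarray(loops[li], dtype=np.int64) for li in sorted(loops)]
    fixed_list = [fixed[li] for li in sorted(loops)]
    return Tissue(
        pos=pos,
        flags=flags,
        types=types,
        A0=A0,
        age=age,
        theta=theta,
        ids=ids,
        loops=loop_list,
        loop_fixed=fixed_list,
        n_types=n_types,
    )


# ---------------------------------------------------------------------------
# event log
# ---------------------------------------------------------------------------

def write_events(events: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("step\ttime\tevent\tids\n")
        for ev in events:
            ids = ",".join(str(i) for i in ev.get("ids", ()))
            fh.write(f"{ev['step']}\t{_FMT % ev['time']}\t{ev['event']}\t{ids}\n")


def read_events(path: str | Path) -> list[dict]:
    out = []
    for ln in Path(path).read_text().splitlines()[1:]:
        if not ln.strip():
            continue
        step, t, event, ids = (ln.split("\t") + [""])[:4]
        out.append(
            {
                "step": int(step),
                "time": float(t),
                "event": event,
                "ids": tuple(int(x) for x in ids.split(",") if x),
            }
        )
    return out


# ---------------------------------------------------------------------------
# trajectory views
# ---------------------------------------------------------------------------

def interior_table(tissue: Tissue):
    """(ids, positions) of interior cells, id-sorted (stable across frames)."""
    idx = tissue.interior_idx
    order = np.argsort(tissue.ids[idx])
    idx = idx[order]
    return tissue.ids[idx].copy(), tissue.pos[idx].copy()


def aligned_positions(frames: list[tuple[np.ndarray, np.ndarray]]):
    """Stack per-frame (ids, positions) into (n_frames, n_common, 2).

    Only cells present in every frame are kept (cells created or destroyed
    mid-window are excluded from scattering averages).
    """
    common = frames[0][0]
    for ids, _ in frames[1:]:
        common = np.intersect1d(common, ids)
    out = np.empty((len(frames), len(common), 2))
    for f, (ids, pos) in enumerate(frames):
        lookup = {int(i): k for k, i in enumerate(ids)}
        sel = [lookup[int(i)] for i in common]
        out[f] = pos[sel]
    return common, out


def save_rng_state(rng: np.random.Generator, path: str | Path) -> None:
    Path(path).write_text(json.dumps(rng.bit_generator.state))


def load_rng_state(path: str | Path) -> np.random.Generator:
    state = json.loads(Path(path).read_text())
    rng = np.random.default_rng()
    rng.bit_generator.state = state
    return rng
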