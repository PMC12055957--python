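"""Content-addressed run cache for forward simulations.

Keys are SHA-1 hashes of a canonical JSON encoding of the run parameters;
values are .npz files under ``scratch/cache`` (or the system temp directory
when the working directory is read-only).  Caching only ever reuses results
of the identical deterministic computation.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile

import numpy as np

_CACHE_DIR: str | None = None


def cache_dir() -> str:
    global _CACHE_DIR
    if _CACHE_DIR is None:
        cand = os.environ.get(
            "CAPSULEFLOW_CACHE", os.path.join(os.getcwd(), "scratch", "cache")
        )
        try:
            os.makedirs(cand, exist_ok=True)
            probe = os.path.join(cand, ".probe")
            with open(probe, "w") as fh:
                fh.write("ok")
            os.remove(probe)
        except OSError:
            cand = os.path.join(tempfile.gettempdir(), "capsuleflow-cache")
            os.makedirs(cand, exist_ok=True)
        _CACHE_DIR = cand
    return _CACHE_DIR


def key_hash(key: dict) -> str:
    blob = json.dumps(key, sort_keys=True, default=float).encode()
    return hashlib.sha1(blob).hexdigest()


def load(key: dict) -> dict | None:
    path = os.path.join(cache_dir(), key_hash(key) + ".npz")
    if not os.path.exists(path):
        return None
    try:
        with np.load(path, allow_pickle=False) as z:
            return {k: z[k] for k in z.files}
    except Exception:
        return None


def save(key: dict, payload: dict) -> None:
    path = os.path.join(cache_dir(), key_hash(key) + ".npz")
    tmp = path + f".tmp{os.getpid()}.npz"  # savez appends .npz otherwise
    np.savez_compressed(tmp, **payload)
    os.replace(tmp, path)
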