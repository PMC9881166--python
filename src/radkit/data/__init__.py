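"""Packaged reference definitions.

Small, versioned text files pinning the residue sets that the decomposition
depends on: the SSU head/body partition and the anchor residues that fix the
zero-tilt (ψ = 0) directions, all in *E. coli* 16S numbering.
"""

from __future__ import annotations

import json
from importlib import resources

__all__ = ["load_head_set", "load_anchors", "HEAD_SET_VERSION"]

HEAD_SET_VERSION = 1


def _read_text(name: str) -> str:
    return resources.files(__package__).joinpath(name).read_text()


def load_head_set(version: int = HEAD_SET_VERSION) -> frozenset[int]:
    """The SSU head residue set (E. coli 16S numbering)."""
    residues: set[int] = set()
    for line in _read_text(f"head_16s_v{version}.txt").splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        start, end = map(int, line.split())
        residues.update(range(start, end + 1))
    return frozenset(residues)


def load_anchors(version: int = HEAD_SET_VERSION) -> dict[str, frozenset[int]]:
    """Zero-tilt anchor residue sets (E. coli 16S numbering)."""
    raw = json.loads(_read_text(f"anchors_16s_v{version}.json"))
    out: dict[str, frozenset[int]] = {}
    for key, val in raw.items():
        if not isinstance(val, dict):
            continue
        residues: set[int] = set(val.get("residues", []))
        for start, end in val.get("ranges", []):
            residues.update(range(start, end + 1))
        out[key] = frozenset(residues)
    return out
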