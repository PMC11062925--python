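"""JSON persistence for vessel trees.

Schema::

    {"root": <id>,
     "segments": [{"id": int, "parent": int|null,
                   "p0": [x,y,z], "p1": [x,y,z],
                   "radius": float, "origin": "image_based"|"synthetic",
                   "perfuses_lv": bool}, ...]}
"""

from __future__ import annotations

import json

from .model import VesselSegment, VesselTree


def write_tree(tree: VesselTree, path) -> None:
    doc = {
        "root": tree.root_id,
        "segments": [
            {
                "id": s.id,
                "parent": s.parent_id,
                "p0": list(s.p0),
                "p1": list(s.p1),
                "radius": s.radius,
                "origin": s.origin_tag,
                "perfuses_lv": s.perfuses_lv,
            }
            for sid, s in sorted(tree.segments.items())
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_tree(path) -> VesselTree:
    with open(path) as fh:
        doc = json.load(fh)
    segs = [
        VesselSegment(
            id=d["id"],
            parent_id=d["parent"],
            p0=d["p0"],
            p1=d["p1"],
            radius=d["radius"],
            origin_tag=d.get("origin", "synthetic"),
            perfuses_lv=d.get("perfuses_lv", True),
        )
        for d in doc["segments"]
    ]
    return VesselTree(segs, doc["root"])
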