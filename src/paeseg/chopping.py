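"""Text encoding of segmentations ("choppings").

A chopping is a semicolon-separated list of ``start-end:kind`` fields with
1-based inclusive coordinates, e.g.::

    1-24:disordered;25-180:domain;181-188:linker;189-305:domain

``parse_chopping(format_chopping(s)) == s`` for every valid segmentation.
"""

from __future__ import annotations

import re

from .segment import Region, Segmentation

__all__ = ["format_chopping", "parse_chopping"]

_FIELD_RE = re.compile(r"^(\d+)-(\d+):(domain|linker|disordered)$")


def format_chopping(seg: Segmentation) -> str:
    """Encode a segmentation as a chopping string."""
    return ";".join(f"{r.start}-{r.end}:{r.kind}" for r in seg.regions)


def parse_chopping(text: str, protein_id: str, length: int) -> Segmentation:
    """Parse a chopping string back into a :class:`Segmentation`.

    Raises ``ValueError`` when fields are malformed, unsorted, overlapping
    or do not cover ``1..length`` exactly.
    """
    regions = []
    for field in text.strip().split(";"):
        m = _FIELD_RE.match(field.strip())
        if m is None:
            raise ValueError(f"malformed chopping field {field!r}")
        start, end, kind = int(m.group(1)), int(m.group(2)), m.group(3)
        regions.append(Region(start=start, end=end, kind=kind))
    return Segmentation(protein_id=protein_id, length=length, regions=tuple(regions))
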