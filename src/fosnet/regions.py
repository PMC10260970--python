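"""Brain-region nomenclature registry and hemispheric node identifiers.

Nodes of the functional networks are *region sides*: a telencephalic or
diencephalic nucleus together with a hemisphere, written ``"<code>_<l|r>"``
(e.g. ``"Vv_l"`` for the left ventral nucleus of the ventral telencephalic
area).  The default registry holds the 35 adult-zebrafish region codes used
for c-fos cell counting; it can be extended for other parcellations.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "REGION_NAMES",
    "REGION_CODES",
    "HEMISPHERES",
    "RegionNode",
    "RegionRegistry",
    "default_registry",
]

# code -> full anatomical name (adult zebrafish brain nomenclature)
REGION_NAMES: dict[str, str] = {
    "OB": "Olfactory bulbs",
    "D": "Dorsal telencephalic area",
    "Vd": "Dorsal nucleus of ventral telencephalic area",
    "Vc": "Central nucleus of ventral telencephalic area",
    "Vv": "Ventral nucleus of ventral telencephalic area",
    "Vl": "Lateral nucleus of ventral telencephalic area",
    "Dc": "Central zone of dorsal telencephalic area",
    "Dl": "Lateral zone of dorsal telencephalic area",
    "Dm": "Medial zone of dorsal telencephalic area",
    "Dp": "Posterior zone of dorsal telencephalic area",
    "Vs": "Supracommissural nucleus of ventral telencephalic area",
    "Dd": "Dorsal zone of dorsal telencephalic area",
    "Ppa": "Anterior part of parvocellular preoptic nucleus",
    "Vp": "Postcommissural nucleus of ventral telencephalic area",
    "PM": "Magnocellular preoptic nucleus",
    "PPp": "Posterior part of parvocellular preoptic nucleus",
    "Had": "Dorsal habenular nucleus",
    "Hav": "Ventral habenular nucleus",
    "A": "Anterior thalamic nucleus",
    "VM": "Ventromedial thalamic nucleus",
    "VL": "Ventrolateral thalamic nucleus",
    "Hv": "Ventral zone of periventricular hypothalamus",
    "ATN": "Anterior tuberal nucleus",
    "LH": "Lateral hypothalamic nucleus",
    "Hd": "Dorsal zone of periventricular hypothalamus",
    "CP": "Central posterior thalamic nucleus",
    "TPp": "Periventricular nucleus of posterior tuberculum",
    "PGZ": "Periventricular gray zone of optic tectum",
    "Hc": "Caudal zone of periventricular hypothalamus",
    "DIL": "Diffuse nucleus of the inferior lobe",
    "DTN": "Dorsal tegmental nucleus",
    "CIL": "Central nucleus of the inferior lobe",
    "NLV": "Nucleus lateralis valvulae",
    "GC": "Griseum centrale",
    "CM": "Corpus mamillare",
}

REGION_CODES: tuple[str, ...] = tuple(REGION_NAMES)
HEMISPHERES: tuple[str, str] = ("l", "r")


@dataclass(frozen=True, order=True)
class RegionNode:
    """One hemispheric region node, e.g. ``RegionNode("Vv", "l")``."""

    region_code: str
    hemisphere: str

    @property
    def node_id(self) -> str:
        return f"{self.region_code}_{self.hemisphere}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.node_id


class RegionRegistry:
    """Known region codes with tolerant canonicalization.

    Lookup is exact first; case differs only between genuinely distinct
    codes in two places (``Vl`` vs ``VL``), so a case-insensitive fallback
    is applied only when it is unambiguous (e.g. ``"Cil"`` -> ``"CIL"``).
    """

    def __init__(self, codes: tuple[str, ...] = REGION_CODES) -> None:
        self.codes = tuple(codes)
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("region codes must be unique")
        self._exact = set(self.codes)
        self._lower: dict[str, list[str]] = {}
        for c in self.codes:
            self._lower.setdefault(c.lower(), []).append(c)

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self._exact or len(self._lower.get(code.lower(), [])) == 1

    def canonical(self, code: str) -> str:
        """Return the canonical spelling of ``code`` or raise ``KeyError``."""
        if code in self._exact:
            return code
        hits = self._lower.get(code.lower(), [])
        if len(hits) == 1:
            return hits[0]
        if len(hits) > 1:
            raise KeyError(
                f"ambiguous region code {code!r}: matches {hits} (case matters here)"
            )
        raise KeyError(
            f"unknown region code {code!r}; known codes: {', '.join(self.codes)}"
        )

    def extended(self, extra_codes) -> "RegionRegistry":
        """A new registry with ``extra_codes`` appended."""
        new = [c for c in extra_codes if c not in self._exact]
        return RegionRegistry(self.codes + tuple(new))

    def make_node(self, region_code: str, hemisphere: str) -> RegionNode:
        hemi = hemisphere.lower()
        if hemi not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}, got {hemisphere!r}")
        return RegionNode(self.canonical(region_code), hemi)

    def parse_node_id(self, node_id: str) -> RegionNode:
        """Parse ``"<code>_<l|r>"`` into a :class:`RegionNode`."""
        code, sep, hemi = node_id.rpartition("_")
        if not sep or hemi.lower() not in HEMISPHERES:
            raise ValueError(
                f"malformed node id {node_id!r}: expected '<region>_<l|r>'"
            )
        return self.make_node(code, hemi)

    def all_nodes(self) -> list[RegionNode]:
        """All hemispheric nodes in registry order (left before right per region)."""
        return [RegionNode(c, h) for c in self.codes for h in HEMISPHERES]


_DEFAULT = RegionRegistry()


def default_registry() -> RegionRegistry:
    """The default 35-code registry."""
    return _DEFAULT
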