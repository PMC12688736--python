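"""Registry of the candidate MRI markers and the numbered model features.

Ten baseline markers are screened (six continuous, four categorical); the
seven that change significantly under chemoradiotherapy carry the model's
feature numbers 1-7. Categorical encodings: N stage in {0,1,2}, T stage in
{2,3,4}, EMVI and CRM in {0,1} (1 = positive/involved).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FeatureSpec:
    """One candidate marker; ``index`` is the model feature number (or None)."""

    name: str
    kind: str  # "continuous" | "ordinal" | "binary"
    units: str
    index: int | None = None
    levels: tuple[int, ...] | None = None
    floor: float | None = None  # physiologic lower bound for simulation

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "ordinal", "binary"):
            raise ValueError(f"unknown marker kind {self.kind!r}")
        if self.kind != "continuous" and self.levels is None:
            raise ValueError(f"categorical marker {self.name!r} needs levels")


#: All ten screened markers, in canonical (report) order.
CANDIDATE_MARKERS: tuple[FeatureSpec, ...] = (
    FeatureSpec("tumor_circumferential_ratio", "continuous", "fraction"),
    FeatureSpec("sagittal_longest_diameter", "continuous", "mm", index=1, floor=0.0),
    FeatureSpec("adc_value", "continuous", "1e-3 mm^2/s", index=2, floor=1e-6),
    FeatureSpec("distance_to_anus", "continuous", "mm", floor=0.0),
    FeatureSpec("lymph_node_number", "continuous", "count", index=3, floor=0.0),
    FeatureSpec("max_lymph_node_diameter", "continuous", "mm", index=4, floor=0.0),
    FeatureSpec("n_stage", "ordinal", "stage level", index=5, levels=(0, 1, 2)),
    FeatureSpec("t_stage", "ordinal", "stage level", levels=(2, 3, 4)),
    FeatureSpec("emvi", "binary", "indicator", index=6, levels=(0, 1)),
    FeatureSpec("crm", "binary", "indicator", index=7, levels=(0, 1)),
)

MARKERS_BY_NAME: dict[str, FeatureSpec] = {m.name: m for m in CANDIDATE_MARKERS}

#: Model feature number -> marker, in the canonical 1..7 numbering.
MODEL_FEATURES: dict[int, FeatureSpec] = {
    m.index: m for m in CANDIDATE_MARKERS if m.index is not None
}

CONTINUOUS_MARKERS: tuple[str, ...] = tuple(
    m.name for m in CANDIDATE_MARKERS if m.kind == "continuous"
)
CATEGORICAL_MARKERS: tuple[str, ...] = tuple(
    m.name for m in CANDIDATE_MARKERS if m.kind != "continuous"
)
MARKER_NAMES: tuple[str, ...] = tuple(m.name for m in CANDIDATE_MARKERS)


def feature_names(indices) -> list[str]:
    """Marker names for model feature indices (1..7), preserving order."""
    out = []
    for i in indices:
        if i not in MODEL_FEATURES:
            raise KeyError(f"unknown model feature index {i}; valid: 1..7")
        out.append(MODEL_FEATURES[i].name)
    return out


def feature_index(name: str) -> int | None:
    """Model feature number of a marker, or None if it is not a model feature."""
    return MARKERS_BY_NAME[name].index
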