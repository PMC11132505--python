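"""LCD class definitions.

An LCD class is named by the amino acid(s) whose windowed composition defines
it: 20 *primary* classes (one per canonical amino acid, single composition
threshold) and 380 ordered *secondary* classes (a primary amino acid at a high
threshold plus a distinct secondary amino acid at a lower threshold). Class
labels are positional: "HQ" is the search with the primary threshold on H and
the secondary threshold on Q, regardless of which residue ends up more
abundant in a detected domain; "QH" is a distinct class.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError

#: The 20 canonical amino acids, alphabetical.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / non-standard letters tolerated in input sequences. They count
#: toward window length but never toward any class composition.
NONCANONICAL_AA = "XUOBZJ"

DEFAULT_WINDOW = 20
DEFAULT_PRIMARY_THRESHOLD = 0.40
DEFAULT_SECONDARY_THRESHOLD = 0.20
DEFAULT_DISPERSION_THRESHOLD = 0.5


@dataclass(frozen=True)
class ClassSpec:
    """Search definition for one of the 400 LCD classes.

    Parameters
    ----------
    primary_aa :
        Canonical amino acid carrying the high composition threshold.
    secondary_aa :
        Optional second canonical amino acid (ordered secondary classes).
    window_size :
        Sliding-window width W in residues.
    primary_threshold, secondary_threshold :
        Minimum windowed composition fractions c1 (and c2 when a secondary
        amino acid is set).
    dispersion_threshold :
        Minimum linear dispersion, applied separately to each amino acid in
        the search.
    """

    primary_aa: str
    secondary_aa: str | None = None
    window_size: int = DEFAULT_WINDOW
    primary_threshold: float = DEFAULT_PRIMARY_THRESHOLD
    secondary_threshold: float = DEFAULT_SECONDARY_THRESHOLD
    dispersion_threshold: float = DEFAULT_DISPERSION_THRESHOLD

    def __post_init__(self) -> None:
        if self.primary_aa not in CANONICAL_AA or len(self.primary_aa) != 1:
            raise ConfigurationError(
                f"primary_aa must be one canonical amino acid, got {self.primary_aa!r}"
            )
        if self.secondary_aa is not None:
            if self.secondary_aa not in CANONICAL_AA or len(self.secondary_aa) != 1:
                raise ConfigurationError(
                    f"secondary_aa must be one canonical amino acid, got {self.secondary_aa!r}"
                )
            if self.secondary_aa == self.primary_aa:
                raise ConfigurationError("primary_aa and secondary_aa must differ")
        if self.window_size < 2:
            raise ConfigurationError("window_size must be >= 2")
        if not 0.0 < self.primary_threshold <= 1.0:
            raise ConfigurationError("primary_threshold must be in (0, 1]")
        if self.secondary_aa is not None:
            if not 0.0 < self.secondary_threshold <= 1.0:
                raise ConfigurationError("secondary_threshold must be in (0, 1]")
            if self.primary_threshold + self.secondary_threshold > 1.0 + 1e-12:
                raise ConfigurationError(
                    "Invalid threshold: primary and secondary composition "
                    "thresholds sum to more than 100%"
                )
        if not 0.0 <= self.dispersion_threshold <= 1.0:
            raise ConfigurationError("dispersion_threshold must be in [0, 1]")

    @property
    def label(self) -> str:
        """Class label: the primary letter, or primary+secondary (e.g. 'HQ')."""
        if self.secondary_aa is None:
            return self.primary_aa
        return self.primary_aa + self.secondary_aa

    @property
    def is_secondary(self) -> bool:
        return self.secondary_aa is not None


def primary_class_labels() -> list[str]:
    return list(CANONICAL_AA)


def secondary_class_labels() -> list[str]:
    return [p + s for p in CANONICAL_AA for s in CANONICAL_AA if s != p]


#: Canonical signature ordering: the 20 primary classes (alphabetical)
#: followed by the 380 secondary classes (lexicographic).
ALL_CLASS_LABELS: tuple[str, ...] = tuple(primary_class_labels() + secondary_class_labels())


def spec_from_label(
    label: str,
    window_size: int = DEFAULT_WINDOW,
    primary_threshold: float = DEFAULT_PRIMARY_THRESHOLD,
    secondary_threshold: float = DEFAULT_SECONDARY_THRESHOLD,
    dispersion_threshold: float = DEFAULT_DISPERSION_THRESHOLD,
) -> ClassSpec:
    """Build a :class:`ClassSpec` from a 1- or 2-letter class label."""
    if len(label) == 1:
        return ClassSpec(label, None, window_size, primary_threshold,
                         secondary_threshold, dispersion_threshold)
    if len(label) == 2:
        return ClassSpec(label[0], label[1], window_size, primary_threshold,
                         secondary_threshold, dispersion_threshold)
    raise ConfigurationError(f"invalid class label {label!r}")


def all_class_specs(
    window_size: int = DEFAULT_WINDOW,
    primary_threshold: float = DEFAULT_PRIMARY_THRESHOLD,
    secondary_threshold: float = DEFAULT_SECONDARY_THRESHOLD,
    dispersion_threshold: float = DEFAULT_DISPERSION_THRESHOLD,
) -> list[ClassSpec]:
    """All 400 class specs (20 primary + 380 secondary) in canonical order."""
    return [
        spec_from_label(lbl, window_size, primary_threshold,
                        secondary_threshold, dispersion_threshold)
        for lbl in ALL_CLASS_LABELS
    ]


def reciprocal_merged_label(label: str) -> str:
    """Canonical label for a reciprocal class pair.

    Secondary classes XY and YX collapse to the alphabetical concatenation
    ``"XY|YX"``; primary labels are returned unchanged.
    """
    if len(label) == 1:
        return label
    pair = sorted((label, label[1] + label[0]))
    return "|".join(pair)
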