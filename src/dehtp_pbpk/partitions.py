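"""Tissue:blood partition-coefficient tables with surrogate fallbacks.

Tissue-composition algorithms do not emit a value for every model
compartment; missing compartments borrow the value of a surrogate organ
with similar perfusion (stomach <- gut, rapidly perfused <- spleen,
slowly perfused <- muscle).  Resolution is a single hop: a surrogate
donor must hold a direct value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["PartitionSet", "DEFAULT_SURROGATES", "default_partition_set"]

DEFAULT_SURROGATES = {
    "stomach": "gut",
    "rapidly_perfused": "spleen",
    "slowly_perfused": "muscle",
}


@dataclass
class PartitionSet:
    """Map of (chemical, tissue) -> tissue:blood partition coefficient."""

    values: dict[tuple[str, str], float] = field(default_factory=dict)
    surrogate_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SURROGATES))

    def __post_init__(self) -> None:
        for key, pc in self.values.items():
            if pc <= 0:
                raise ValueError(f"partition coefficient for {key} must be > 0")
        for tissue, donor in self.surrogate_map.items():
            if self.surrogate_map.get(donor) is not None:
                raise ValueError(
                    f"surrogate chain {tissue} -> {donor} -> ... : at most one hop allowed"
                )

    def set(self, chemical: str, tissue: str, pc: float) -> None:
        if pc <= 0:
            raise ValueError("partition coefficient must be > 0")
        self.values[(chemical, tissue)] = pc

    def get(self, chemical: str, tissue: str) -> float:
        """Direct value if present, else the surrogate donor's value."""
        if (chemical, tissue) in self.values:
            return self.values[(chemical, tissue)]
        donor = self.surrogate_map.get(tissue)
        if donor is not None and (chemical, donor) in self.values:
            return self.values[(chemical, donor)]
        raise KeyError(f"no partition coefficient for {chemical}/{tissue} (no surrogate)")

    def resolved_from(self, chemical: str, tissue: str) -> str:
        """The tissue whose value answers a lookup (itself or its donor)."""
        if (chemical, tissue) in self.values:
            return tissue
        donor = self.surrogate_map.get(tissue)
        if donor is not None and (chemical, donor) in self.values:
            return donor
        raise KeyError(f"no partition coefficient for {chemical}/{tissue}")


#: In-silico predicted tissue:blood PCs (direct entries only; stomach,
#: rapidly and slowly perfused resolve through surrogates).
_PREDICTED = {
    ("DEHTP", "adipose"): 47.2,
    ("DEHTP", "kidney"): 3.7,
    ("DEHTP", "liver"): 5.9,
    ("DEHTP", "muscle"): 3.3,
    ("DEHTP", "blood_cells"): 3.0,
    ("DEHTP", "gut"): 7.4,
    ("DEHTP", "spleen"): 3.7,
    ("MEHTP", "adipose"): 20.3,
    ("MEHTP", "kidney"): 12.2,
    ("MEHTP", "liver"): 5.9,
    ("MEHTP", "muscle"): 3.3,
    ("MEHTP", "blood_cells"): 3.0,
    ("MEHTP", "gut"): 7.4,
    ("MEHTP", "spleen"): 3.7,
}


def default_partition_set() -> PartitionSet:
    """The in-silico predicted table for DEHTP and MEHTP."""
    return PartitionSet(values=dict(_PREDICTED))
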