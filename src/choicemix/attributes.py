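"""Attribute/level specification and difference coding for paired choice tasks.

An experiment is an ordered list of :class:`AttributeSpec`. Continuous
attributes contribute one coded column equal to the raw level difference
divided by ``model_scale``; categorical attributes contribute one dummy
column per non-reference level (so a level change appears as a -1/0/+1
dummy difference). The coded column order is fixed: attributes in list
order, and within a categorical attribute the order of ``dummy_levels``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml


class AttributeError_(ValueError):
    """Invalid attribute specification or illegal level, naming the attribute."""


@dataclass(frozen=True)
class AttributeSpec:
    """One choice attribute: its levels and how it enters the model.

    Parameters
    ----------
    name:
        Identifier; for continuous attributes also the coded column name.
    kind:
        ``"continuous"`` or ``"categorical"``.
    levels:
        Ordered list of 2 or 3 distinct raw level values.
    model_scale:
        Positive divisor applied to raw differences (continuous only),
        e.g. cattle are modelled per 100 head.
    reference_level:
        The level coded as all-zero (categorical only).
    dummy_levels:
        Ordered (level, column_name) pairs for the non-reference levels
        (categorical only). Defaults to each non-reference level in
        ``levels`` order with column name ``f"{name}_{level}"``.
    """

    name: str
    kind: str
    levels: tuple
    model_scale: float = 1.0
    reference_level: object = None
    dummy_levels: tuple = field(default=None)

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical"):
            raise AttributeError_(f"{self.name}: kind must be continuous or categorical")
        levels = tuple(self.levels)
        object.__setattr__(self, "levels", levels)
        if not 2 <= len(levels) <= 3:
            raise AttributeError_(f"{self.name}: needs 2 or 3 levels, got {len(levels)}")
        if len(set(levels)) != len(levels):
            raise AttributeError_(f"{self.name}: levels must be distinct")
        if self.model_scale <= 0:
            raise AttributeError_(f"{self.name}: model_scale must be positive")
        if self.kind == "categorical":
            if self.reference_level not in levels:
                raise AttributeError_(
                    f"{self.name}: reference_level {self.reference_level!r} not a level"
                )
            if self.dummy_levels is None:
                dl = tuple(
                    (lev, f"{self.name}_{lev}") for lev in levels if lev != self.reference_level
                )
                object.__setattr__(self, "dummy_levels", dl)
            else:
                dl = tuple((lev, col) for lev, col in self.dummy_levels)
                object.__setattr__(self, "dummy_levels", dl)
                bad = [lev for lev, _ in dl if lev not in levels or lev == self.reference_level]
                if bad or len(dl) != len(levels) - 1:
                    raise AttributeError_(f"{self.name}: dummy_levels must cover the "
                                          "non-reference levels exactly once")
        else:
            if self.reference_level is not None:
                raise AttributeError_(f"{self.name}: continuous attributes take no reference level")
            try:
                [float(v) for v in levels]
            except (TypeError, ValueError):
                raise AttributeError_(f"{self.name}: continuous levels must be numeric") from None

    @property
    def columns(self) -> list[str]:
        """Coded column names this attribute contributes, in order."""
        if self.kind == "continuous":
            return [self.name]
        return [col for _, col in self.dummy_levels]

    def code_level(self, level) -> list[float]:
        """Coded representation of one raw level (before differencing)."""
        if level not in self.levels:
            raise AttributeError_(f"{self.name}: illegal level {level!r}")
        if self.kind == "continuous":
            return [float(level) / self.model_scale]
        return [1.0 if level == lev else 0.0 for lev, _ in self.dummy_levels]


def coded_columns(attrs: Sequence[AttributeSpec]) -> list[str]:
    """Fixed coded column order for a list of attributes."""
    cols: list[str] = []
    for a in attrs:
        cols.extend(a.columns)
    return cols


def default_attributes() -> list[AttributeSpec]:
    """The six-attribute livelihood experiment.

    Access to conservancy grazing in drought (yes/no), cattle owned
    (0/40/100, per 100 head), conservancy involvement (none / half of a
    150-acre holding for 9,000 KSh / all of it for 18,000 KSh),
    subsistence cultivation (none / 5 acres), small stock (0/80/200,
    per 200 head) and monthly wage (0/6,000/10,000 KSh, per 10,000 KSh).
    Coded columns: access, cattle, cons150, cons75, cult, smlstk, wage.
    """
    return [
        AttributeSpec("access", "categorical", ("prohibited", "allowed"),
                      reference_level="prohibited", dummy_levels=(("allowed", "access"),)),
        AttributeSpec("cattle", "continuous", (0, 40, 100), model_scale=100.0),
        AttributeSpec("cons", "categorical", ("none", "half", "full"),
                      reference_level="none",
                      dummy_levels=(("full", "cons150"), ("half", "cons75"))),
        AttributeSpec("cult", "categorical", ("none", "5acres"),
                      reference_level="none", dummy_levels=(("5acres", "cult"),)),
        AttributeSpec("smlstk", "continuous", (0, 80, 200), model_scale=200.0),
        AttributeSpec("wage", "continuous", (0, 6000, 10000), model_scale=10000.0),
    ]


def load_attributes(path: str | Path) -> list[AttributeSpec]:
    """Read an attribute specification from a YAML or JSON config file.

    The file holds a list of mappings with keys ``name``, ``kind``,
    ``levels`` and optionally ``scale``, ``reference``, ``dummies``
    (mapping of level -> coded column name, in column order).
    """
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    attrs = []
    for item in data:
        dummies = item.get("dummies")
        dummy_levels = tuple(dummies.items()) if dummies else None
        attrs.append(AttributeSpec(
            name=item["name"],
            kind=item["kind"],
            levels=tuple(item["levels"]),
            model_scale=float(item.get("scale", 1.0)),
            reference_level=item.get("reference"),
            dummy_levels=dummy_levels,
        ))
    return attrs


def dump_attributes(attrs: Sequence[AttributeSpec], path: str | Path) -> None:
    """Write an attribute specification config (YAML)."""
    data = []
    for a in attrs:
        item = {"name": a.name, "kind": a.kind, "levels": list(a.levels)}
        if a.kind == "continuous":
            item["scale"] = a.model_scale
        else:
            item["reference"] = a.reference_level
            item["dummies"] = {lev: col for lev, col in a.dummy_levels}
        data.append(item)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
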