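"""Per-patient labelled transition systems from discretised feature traces.

Each patient becomes a finite linear LTS: slices are visited in
cranio-caudal order and, within a slice, the selected features in canonical
order; every feature observation is one action symbol ``feature=Lk`` where
``k`` is the quantile level of the value under a training-set
discretisation scheme.  The chain has ``n_slices * n_features`` transitions
and one more state, with state 0 initial.

Serialisation uses the Aldebaran ``.aut`` format:

    des (0, <n_transitions>, <n_states>)
    (<src>, "<action>", <dst>)
    ...
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DiscretizationScheme",
    "PatientLTS",
    "fit_discretization",
    "discretize_value",
    "discretize_trace",
    "build_patient_lts",
    "write_aut",
    "read_aut",
]


@dataclass(frozen=True)
class DiscretizationScheme:
    """Per-feature quantile cut points mapping values to levels L1..LK.

    Cuts are fitted on pooled training-slice values (both classes).  The tie
    rule is left-closed: a value equal to a cut maps to the lower level.
    Duplicate quantiles collapse, so a feature may occupy fewer than K
    levels.
    """

    features: tuple[str, ...]
    cuts: dict[str, tuple[float, ...]]
    n_levels: int

    def level(self, feature: str, value: float) -> int:
        cut = self.cuts[feature]
        if np.isnan(value):
            warnings.warn(f"NaN value for {feature}; mapped to L1")
            return 1
        return 1 + int(sum(value > c for c in cut))

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_levels": self.n_levels,
                "features": list(self.features),
                "cuts": {f: list(c) for f, c in self.cuts.items()},
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "DiscretizationScheme":
        d = json.loads(text)
        return cls(
            features=tuple(d["features"]),
            cuts={f: tuple(c) for f, c in d["cuts"].items()},
            n_levels=int(d["n_levels"]),
        )


def fit_discretization(
    table: pd.DataFrame, features: list[str] | tuple[str, ...], n_levels: int = 5
) -> DiscretizationScheme:
    """Fit per-feature cut points at the 1/K .. (K-1)/K pooled quantiles.

    ``table`` holds the training patients' slice rows.  Features with fewer
    distinct values than levels may produce duplicate quantiles, which are
    collapsed with a warning.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if len(table) == 0:
        raise ValueError("empty training table")
    qs = np.arange(1, n_levels) / n_levels
    cuts: dict[str, tuple[float, ...]] = {}
    for f in features:
        if f not in table.columns:
            raise ValueError(f"feature {f!r} missing from training table")
        values = table[f].to_numpy(dtype=float)
        values = values[~np.isnan(values)]
        if values.size == 0:
            raise ValueError(f"feature {f!r} has no finite training value")
        raw = np.quantile(values, qs)
        dedup = tuple(dict.fromkeys(float(c) for c in raw))
        if len(dedup) < len(raw):
            warnings.warn(f"feature {f!r}: duplicate quantile cuts collapsed")
        cuts[f] = dedup
    return DiscretizationScheme(features=tuple(features), cuts=cuts, n_levels=n_levels)


def discretize_value(scheme: DiscretizationScheme, feature: str, value: float) -> str:
    return f"{feature}=L{scheme.level(feature, value)}"


def discretize_trace(table: pd.DataFrame, scheme: DiscretizationScheme) -> list[str]:
    """Action symbols of one patient, slice-major, features in scheme order."""
    missing = [f for f in scheme.features if f not in table.columns]
    if missing:
        raise ValueError(f"patient table missing features: {missing}")
    n_rows = len(table)
    per_feature = []
    for f in scheme.features:
        values = table[f].to_numpy(dtype=float)
        nan = np.isnan(values)
        if nan.any():
            warnings.warn(f"NaN values for {f}; mapped to L1")
        # left-closed tie rule: level = 1 + #{cuts < value}
        lv = 1 + np.searchsorted(np.asarray(scheme.cuts[f]), values, side="left")
        lv[nan] = 1
        per_feature.append([f"{f}=L{k}" for k in lv])
    symbols: list[str] = []
    for i in range(n_rows):
        symbols.extend(col[i] for col in per_feature)
    return symbols


@dataclass(frozen=True)
class PatientLTS:
    """A finite LTS; here always a linear chain with initial state 0."""

    n_states: int
    transitions: tuple[tuple[int, str, int], ...]
    patient_id: str = ""
    initial: int = 0

    def __post_init__(self) -> None:
        for src, _, dst in self.transitions:
            if not (0 <= src < self.n_states and 0 <= dst < self.n_states):
                raise ValueError("transition endpoint out of range")

    @property
    def actions(self) -> tuple[str, ...]:
        return tuple(a for _, a, _ in self.transitions)

    def is_chain(self) -> bool:
        out_deg = np.zeros(self.n_states, dtype=int)
        for src, _, _ in self.transitions:
            out_deg[src] += 1
        return bool((out_deg <= 1).all()) and all(
            (src, dst) == (i, i + 1)
            for i, (src, _, dst) in enumerate(self.transitions)
        )


def build_patient_lts(symbols: list[str], patient_id: str = "") -> PatientLTS:
    """Chain LTS s0 -a1-> s1 ... -an-> sn from an action list (possibly empty)."""
    transitions = tuple((i, a, i + 1) for i, a in enumerate(symbols))
    return PatientLTS(
        n_states=len(symbols) + 1, transitions=transitions, patient_id=patient_id
    )


def write_aut(lts: PatientLTS, path: str | Path) -> None:
    lines = [f"des ({lts.initial}, {len(lts.transitions)}, {lts.n_states})"]
    for src, action, dst in lts.transitions:
        if '"' in action:
            raise ValueError("action labels may not contain double quotes")
        lines.append(f'({src}, "{action}", {dst})')
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_AUT_HEADER = re.compile(r"^des\s*\(\s*(\d+)\s*,\s*(\d+)\s*,\s*(\d+)\s*\)\s*$")
_AUT_EDGE = re.compile(r'^\(\s*(\d+)\s*,\s*"([^"]*)"\s*,\s*(\d+)\s*\)\s*$')


def read_aut(path: str | Path, patient_id: str = "") -> PatientLTS:
    lines = [ln for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty .aut file")
    m = _AUT_HEADER.match(lines[0])
    if not m:
        raise ValueError(f"bad .aut header: {lines[0]!r}")
    initial, n_trans, n_states = (int(g) for g in m.groups())
    transitions = []
    for ln in lines[1:]:
        e = _AUT_EDGE.match(ln)
        if not e:
            raise ValueError(f"bad .aut transition line: {ln!r}")
        transitions.append((int(e.group(1)), e.group(2), int(e.group(3))))
    if len(transitions) != n_trans:
        raise ValueError("transition count does not match header")
    pid = patient_id or Path(path).stem
    return PatientLTS(
        n_states=n_states, transitions=tuple(transitions),
        patient_id=pid, initial=initial,
    )
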