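"""Computed ABC analysis: partition positive scores into A, B and C.

Items are sorted by descending value and the cumulative effort-yield
curve (x_i = i/n, y_i = S_i/S_n) is examined for two landmarks:

* the *Pareto point*, the curve vertex closest to the ideal (0, 1);
* the *break-even point*, where the marginal gain of the next item drops
  to that of a uniform distribution (segment slope n * v_i / S_n <= 1) —
  the boundary sits just before the first such item.

The A|B limit is the smaller of the two x-positions and the B|C limit the
larger, so set A holds "the important few", C "the trivial many" and B
the balance in between.  Items sharing one value never split across sets:
a tied group straddling a limit is demoted whole toward C.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .evidence import SettingsMatrix


@dataclass
class AbcResult:
    items: list[str]  # descending-value order (id tiebreak)
    values: list[float]  # aligned with items
    curve: list[tuple[float, float]]  # (effort x, yield y), starts at (0,0)
    pareto_point: tuple[float, float]
    break_even_x: float
    ab_x: float
    bc_x: float
    sets: dict[str, str]  # item -> "A" | "B" | "C"

    def members(self, label: str) -> list[str]:
        return [i for i in self.items if self.sets[i] == label]

    @property
    def selected(self) -> list[str]:
        """A union B, in descending-value order."""
        return [i for i in self.items if self.sets[i] in ("A", "B")]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "curve": self.curve,
                    "pareto_point": self.pareto_point,
                    "break_even_x": self.break_even_x,
                    "limits": {"ab_x": self.ab_x, "bc_x": self.bc_x},
                    "sets": self.sets,
                },
                fh,
                indent=2,
            )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("item\tvalue\tset\n")
            for item, value in zip(self.items, self.values):
                fh.write(f"{item}\t{value:g}\t{self.sets[item]}\n")


def _sorted_items(values: Mapping[str, float] | Sequence[float]):
    if isinstance(values, Mapping):
        pairs = [(str(k), float(v)) for k, v in values.items()]
    else:
        pairs = [(str(i), float(v)) for i, v in enumerate(values)]
    if not pairs:
        raise ValueError("ABC analysis requires at least one item")
    for item, v in pairs:
        if not (v > 0) or math.isinf(v):
            raise ValueError(f"ABC analysis requires positive values; {item!r} = {v}")
    pairs.sort(key=lambda p: (-p[1], p[0]))
    return pairs


def abc_curve(values) -> list[tuple[float, float]]:
    """Cumulative effort-yield curve points (0,0), (1/n, S_1/S_n), ..., (1,1)."""
    pairs = _sorted_items(values)
    n = len(pairs)
    total = sum(v for _, v in pairs)
    curve = [(0.0, 0.0)]
    acc = 0.0
    for i, (_, v) in enumerate(pairs, start=1):
        acc += v
        curve.append((i / n, acc / total))
    return curve


def abc_analysis(values) -> AbcResult:
    """Run computed ABC analysis on positive item scores."""
    pairs = _sorted_items(values)
    items = [p[0] for p in pairs]
    vals = [p[1] for p in pairs]
    n = len(pairs)
    total = sum(vals)
    curve: list[tuple[float, float]] = [(0.0, 0.0)]
    acc = 0.0
    for i, v in enumerate(vals, start=1):
        acc += v
        curve.append((i / n, acc / total))

    # Pareto point: curve vertex nearest (0, 1); earliest on ties.
    best_d = math.inf
    pareto = curve[0]
    for x, y in curve:
        d = x * x + (1.0 - y) * (1.0 - y)
        if d < best_d - 1e-15:
            best_d = d
            pareto = (x, y)

    # Break-even: boundary just before the first item whose marginal slope
    # n * v_i / S_n falls to <= 1 (uniform gain); x = (i - 1) / n.
    break_even_x = 1.0
    for i, v in enumerate(vals, start=1):
        if n * v / total <= 1.0 + 1e-12:
            break_even_x = (i - 1) / n
            break

    ab_x = min(break_even_x, pareto[0])
    bc_x = max(break_even_x, pareto[0])

    # positional assignment, then whole-group demotion on ties
    eps = 1e-12
    sets: dict[str, str] = {}
    for i, item in enumerate(items, start=1):
        x = i / n
        if x <= ab_x + eps:
            sets[item] = "A"
        elif x <= bc_x + eps:
            sets[item] = "B"
        else:
            sets[item] = "C"

    # group items by value; a straddling group moves whole toward C
    groups: dict[float, list[str]] = {}
    for item, v in zip(items, vals):
        groups.setdefault(v, []).append(item)
    for members in groups.values():
        labels = {sets[m] for m in members}
        if len(labels) > 1:
            demoted = "C" if "C" in labels else "B"
            for m in members:
                sets[m] = demoted

    return AbcResult(
        items=items,
        values=vals,
        curve=curve,
        pareto_point=pareto,
        break_even_x=break_even_x,
        ab_x=ab_x,
        bc_x=bc_x,
        sets=sets,
    )


def select_informative(matrix: SettingsMatrix) -> list[str]:
    """Genes in ABC sets A or B of the per-gene clinical-setting counts."""
    sums = matrix.column_sums
    result = abc_analysis({g: float(s) for g, s in sums.items()})
    return result.selected
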