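"""Light/heavy dimethyl quantification of matched peak-group pairs.

Peptides dimethylated with light (+28 Da) or heavy (+34 Da) tags are paired
by their label-stripped modified sequence and charge. Each side's peak area
is the sum of its M, M+1 and M+2 XIC areas, and the pair is summarised by
the log area ratio (MA-plot y-axis) against the mean log intensity (x-axis).
In an equal-mix experiment the log ratios should centre on zero; peaks that
distort the ratio are exactly what the unanimous classifier vote is meant
to exclude.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._domain import PrecursorPeakGroup
from .errors import AmbiguousPairError, ZeroAreaError

__all__ = [
    "QuantPair",
    "PairCandidate",
    "ANNOTATION_PRESET",
    "QUANT_PRESET",
    "strip_label_tags",
    "match_label_pairs",
    "quantify_pair",
    "quantify_pairs",
    "conventional_filter",
    "summarize_quant",
    "selection_breakdown",
    "plot_ma",
]

#: (idotp_min, |mass error| max in ppm) used to annotate the training set
ANNOTATION_PRESET = (0.85, 10.0)
#: stricter preset used for quantification runs
QUANT_PRESET = (0.9, 6.0)

_LABEL_TAG = re.compile(r"\[\s*\+\s*\d+(?:\.\d+)?\s*\]")


def strip_label_tags(sequence: str) -> str:
    """Remove dimethyl mass-tag annotations (e.g. ``K[+28]``, ``K[+34.06]``)
    so light and heavy forms share one pairing key."""
    return _LABEL_TAG.sub("", sequence)


@dataclass(frozen=True)
class PairCandidate:
    """A matched light/heavy pair before area arithmetic."""

    sequence: str  # label-stripped
    charge: int
    light: PrecursorPeakGroup
    heavy: PrecursorPeakGroup


@dataclass(frozen=True)
class QuantPair:
    """One quantified light/heavy pair."""

    modified_sequence: str
    charge: int
    light_area: float
    heavy_area: float
    log_ratio: float
    mean_log_intensity: float
    log_base: float = 2.0


def match_label_pairs(
    groups: Iterable[PrecursorPeakGroup],
) -> tuple[list[PairCandidate], list[tuple[tuple[str, int], str]]]:
    """Pair light and heavy peak groups on (label-stripped sequence, charge).

    Returns the candidates plus an exclusion list of ``(key, reason)`` for
    groups lacking a partner. A duplicate light (or heavy) group for one key
    raises :class:`AmbiguousPairError`.
    """
    by_key: dict[tuple[str, int], dict[str, list[PrecursorPeakGroup]]] = {}
    for g in groups:
        if g.label_type not in ("light", "heavy"):
            continue
        key = (strip_label_tags(g.modified_sequence), g.charge)
        by_key.setdefault(key, {"light": [], "heavy": []})[g.label_type].append(g)

    candidates: list[PairCandidate] = []
    exclusions: list[tuple[tuple[str, int], str]] = []
    for key in sorted(by_key):
        sides = by_key[key]
        for side in ("light", "heavy"):
            if len(sides[side]) > 1:
                raise AmbiguousPairError(
                    f"{len(sides[side])} {side} groups for key {key}"
                )
        if sides["light"] and sides["heavy"]:
            candidates.append(
                PairCandidate(key[0], key[1], sides["light"][0], sides["heavy"][0])
            )
        else:
            present = "light" if sides["light"] else "heavy"
            exclusions.append((key, f"only the {present} partner was identified"))
    return candidates, exclusions


def quantify_pair(candidate: PairCandidate, log_base: float = 2.0) -> QuantPair:
    """Compute areas and the log ratio for one candidate.

    Each side's area is the sum of its M, M+1, M+2 XIC areas (missing
    isotopes contribute 0). A zero or negative total on either side raises
    :class:`ZeroAreaError` — such pairs are dropped, not zero-filled.
    """
    light = candidate.light.total_area()
    heavy = candidate.heavy.total_area()
    if light <= 0 or heavy <= 0:
        raise ZeroAreaError(
            f"pair ({candidate.sequence}, {candidate.charge}): "
            f"light area {light}, heavy area {heavy}"
        )
    log = lambda v: math.log(v, log_base)  # noqa: E731
    return QuantPair(
        modified_sequence=candidate.sequence,
        charge=candidate.charge,
        light_area=light,
        heavy_area=heavy,
        log_ratio=log(light) - log(heavy),
        mean_log_intensity=0.5 * (log(light) + log(heavy)),
        log_base=log_base,
    )


def quantify_pairs(
    candidates: Sequence[PairCandidate], log_base: float = 2.0
) -> tuple[list[QuantPair], list[tuple[tuple[str, int], str]]]:
    """Quantify all candidates, collecting dropped pairs with reasons."""
    pairs, drops = [], []
    for cand in candidates:
        try:
            pairs.append(quantify_pair(cand, log_base))
        except ZeroAreaError as exc:
            drops.append(((cand.sequence, cand.charge), str(exc)))
    return pairs, drops


def conventional_filter(
    group: PrecursorPeakGroup,
    idotp_min: float = QUANT_PRESET[0],
    abs_mass_error_max_ppm: float = QUANT_PRESET[1],
) -> bool:
    """The conventional acceptance rule: idotP >= threshold and
    |mass error| <= threshold (both boundary-inclusive). Missing values fail."""
    if group.idotp is None:
        return False
    err = group.mass_error_ppm
    if isinstance(err, dict):
        vals = [v for v in err.values() if v is not None]
        if not vals:
            return False
        err = float(np.mean(vals))
    if err is None:
        return False
    return group.idotp >= idotp_min and abs(err) <= abs_mass_error_max_ppm


def selection_breakdown(
    unanimous: Sequence[bool], conventional: Sequence[bool]
) -> dict[str, np.ndarray]:
    """Masks for the three-way MA-plot colouring: pairs selected only by the
    unanimous vote, only by the conventional criteria, or by both."""
    u = np.asarray(unanimous, dtype=bool)
    c = np.asarray(conventional, dtype=bool)
    if u.shape != c.shape:
        raise ValueError("selection flags must align")
    return {"unanimous_only": u & ~c, "conventional_only": c & ~u, "both": u & c}


def summarize_quant(
    pairs: Sequence[QuantPair],
    selections: Optional[Mapping[str, Sequence[bool]]] = None,
) -> pd.DataFrame:
    """Per-selection-set summary of the log ratios.

    One row per selection set (plus ``all``): the pair count, the mean log
    ratio, its population SD across pairs, and the standard error of the
    mean — the two common readings of a reported "deviation".
    """
    if len(pairs) == 0:
        raise ValueError("no quantified pairs to summarize")
    ratios = np.array([p.log_ratio for p in pairs])
    sets: dict[str, np.ndarray] = {"all": np.ones(len(pairs), dtype=bool)}
    if selections is not None:
        for name, mask in selections.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != ratios.shape:
                raise ValueError(f"selection {name!r} does not align with pairs")
            sets[name] = mask
    rows = []
    for name, mask in sets.items():
        sel = ratios[mask]
        n = int(sel.size)
        rows.append(
            {
                "selection": name,
                "n": n,
                "mean_log_ratio": float(sel.mean()) if n else np.nan,
                "sd_log_ratio": float(sel.std()) if n else np.nan,  # population SD
                "sem_log_ratio": float(sel.std() / np.sqrt(n)) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def ma_table(pairs: Sequence[QuantPair]) -> pd.DataFrame:
    """MA-plot coordinates (A = mean log intensity, M = log ratio) per pair."""
    return pd.DataFrame(
        {
            "modified_sequence": [p.modified_sequence for p in pairs],
            "charge": [p.charge for p in pairs],
            "A": [p.mean_log_intensity for p in pairs],
            "M": [p.log_ratio for p in pairs],
        }
    )


def plot_ma(
    pairs: Sequence[QuantPair],
    selections: Mapping[str, Sequence[bool]],
    path: str,
) -> None:
    """Save an MA scatter plot with the three-way selection colouring."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = ma_table(pairs)
    colors = {"both": "0.6", "unanimous_only": "tab:blue", "conventional_only": "tab:red"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, mask in selections.items():
        mask = np.asarray(mask, dtype=bool)
        ax.scatter(
            tab["A"][mask], tab["M"][mask], s=8, alpha=0.7,
            color=colors.get(name), label=name.replace("_", " "),
        )
    ax.axhline(0.0, color="k", lw=0.8, ls="--")
    base = pairs[0].log_base if pairs else 2
    ax.set_xlabel(f"mean log{base:g} intensity (A)")
    ax.set_ylabel(f"log{base:g} light/heavy ratio (M)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
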