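"""Residue hydropathy scales and combined scores for chaperone loop motifs.

The central quantity is the *combined hydropathy* of a set of three short
loop motifs plus the single anchor residue at position 206 of the Bri2
BRICHOS domain: the sum of per-residue scale values over all residues of
motifs 1-3 and the anchor.  Two scales are packaged:

``kyte_doolittle``
    The classic Kyte-Doolittle hydropathy index (dimensionless, larger =
    more hydrophobic).

``biological``
    The translocon-based "biological" hydrophobicity scale: the apparent
    free energy of membrane insertion of each residue via the Sec61
    translocon, in kcal/mol (negative = favourable insertion = hydrophobic).
    It is exposed *negated* so that both scales share the orientation
    larger = more hydrophobic; the published raw values are retained on the
    scale object.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ScaleError, SequenceError

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Builtin scale name -> (packaged table, whether raw values need negation).
_BUILTIN_SCALES = {
    "kyte_doolittle": ("kyte_doolittle.tsv", False),
    "kd": ("kyte_doolittle.tsv", False),
    "biological": ("biological_dg_app.tsv", True),
}


@dataclass(frozen=True)
class HydropathyScale:
    """A per-residue hydropathy scale with a declared orientation.

    ``values`` are always on the orientation stated by
    ``higher_is_hydrophobic``; for scales published on the opposite
    convention (the biological ΔG_app scale) the published numbers are kept
    in ``raw_values``.
    """

    name: str
    values: Mapping[str, float]
    higher_is_hydrophobic: bool = True
    raw_values: Mapping[str, float] | None = None

    def __post_init__(self):
        missing = STANDARD_RESIDUES - set(self.values)
        if missing:
            raise ScaleError(
                f"scale '{self.name}' missing residues: {sorted(missing)}"
            )

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise SequenceError(
                f"residue '{residue}' is not a standard one-letter code"
            ) from None

    def score(self, sequence: str) -> float:
        """Sum of per-residue values over ``sequence`` (empty -> 0.0)."""
        return float(sum(self[r] for r in sequence))


def _read_scale_table(source) -> dict[str, float]:
    if isinstance(source, Mapping):
        items = list(source.items())
    else:
        df = pd.read_csv(source, sep="\t", dtype={"residue": str})
        if not {"residue", "value"} <= set(df.columns):
            raise ScaleError("scale table needs 'residue' and 'value' columns")
        items = list(zip(df["residue"], df["value"].astype(float)))
    values: dict[str, float] = {}
    for res, val in items:
        res = str(res).strip().upper()
        if res in values:
            raise ScaleError(f"duplicate scale entry for residue '{res}'")
        if res not in STANDARD_RESIDUES:
            raise ScaleError(f"non-standard residue '{res}' in scale table")
        values[res] = float(val)
    missing = STANDARD_RESIDUES - set(values)
    if missing:
        raise ScaleError(f"scale table missing residues: {sorted(missing)}")
    return values


def load_scale(name: str, source=None) -> HydropathyScale:
    """Load a hydropathy scale by name or from a user table.

    Parameters
    ----------
    name
        ``"kyte_doolittle"`` (alias ``"kd"``) or ``"biological"`` for the
        packaged scales, or any identifier when ``source`` is given.
    source
        Optional path to a two-column TSV (``residue``, ``value``) or a
        mapping residue -> value.  When given, the table is loaded as-is
        with orientation larger = more hydrophobic.
    """
    if source is not None:
        return HydropathyScale(name=name, values=_read_scale_table(source))
    key = name.lower()
    if key not in _BUILTIN_SCALES:
        raise ScaleError(
            f"unknown scale '{name}'; builtins: kyte_doolittle, biological"
        )
    fname, negate = _BUILTIN_SCALES[key]
    with resources.files("loopchap.data").joinpath(fname).open() as fh:
        raw = _read_scale_table(fh)
    if negate:
        return HydropathyScale(
            name="biological",
            values={r: -v for r, v in raw.items()},
            raw_values=raw,
        )
    return HydropathyScale(name="kyte_doolittle", values=raw)


@dataclass(frozen=True)
class MotifSet:
    """Three loop tripeptide motifs plus the position-206 anchor residue.

    Deletion (ΔL, delta-loop) variants are represented with three empty
    motifs; the anchor may also be empty.
    """

    variant_id: str
    motif1: str = ""
    motif2: str = ""
    motif3: str = ""
    anchor206: str = ""

    def __post_init__(self):
        for name in ("motif1", "motif2", "motif3", "anchor206"):
            seq = getattr(self, name).upper()
            object.__setattr__(self, name, seq)
            bad = set(seq) - STANDARD_RESIDUES
            if bad:
                raise SequenceError(
                    f"{self.variant_id}.{name}: invalid residues {sorted(bad)}"
                )
        if len(self.anchor206) > 1:
            raise SequenceError(
                f"{self.variant_id}: anchor206 must be a single residue or empty"
            )

    @property
    def motifs(self) -> tuple[str, str, str]:
        return (self.motif1, self.motif2, self.motif3)

    @property
    def residues(self) -> str:
        return self.motif1 + self.motif2 + self.motif3 + self.anchor206


@dataclass(frozen=True)
class HydropathyScore:
    variant_id: str
    scale_name: str
    combined: float
    per_motif: tuple[float, float, float]
    anchor: float = 0.0


def motif_hydropathy(motifs: MotifSet, scale: HydropathyScale) -> HydropathyScore:
    """Combined hydropathy of a motif set: Σ scale over motifs 1-3 + anchor."""
    per = tuple(scale.score(m) for m in motifs.motifs)
    anchor = scale.score(motifs.anchor206)
    return HydropathyScore(
        variant_id=motifs.variant_id,
        scale_name=scale.name,
        combined=float(sum(per) + anchor),
        per_motif=per,
        anchor=anchor,
    )


def score_panel(panel: Iterable[MotifSet], scale: HydropathyScale) -> pd.DataFrame:
    """Score a panel of variants; one row per variant, input order kept."""
    panel = list(panel)
    ids = [m.variant_id for m in panel]
    dupes = {v for v in ids if ids.count(v) > 1}
    if dupes:
        raise SequenceError(f"duplicate variant_id(s): {sorted(dupes)}")
    rows = []
    for m in panel:
        s = motif_hydropathy(m, scale)
        rows.append(
            {
                "variant_id": s.variant_id,
                "scale_name": s.scale_name,
                "combined": s.combined,
                "motif1_score": s.per_motif[0],
                "motif2_score": s.per_motif[1],
                "motif3_score": s.per_motif[2],
                "anchor_score": s.anchor,
            }
        )
    return pd.DataFrame(rows)


def read_motif_table(path: str | Path) -> list[MotifSet]:
    """Read a TSV with columns variant_id, motif1, motif2, motif3, anchor206."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"variant_id", "motif1", "motif2", "motif3", "anchor206"}
    if not required <= set(df.columns):
        raise SequenceError(f"motif table needs columns {sorted(required)}")
    return [
        MotifSet(
            variant_id=row.variant_id,
            motif1=row.motif1,
            motif2=row.motif2,
            motif3=row.motif3,
            anchor206=row.anchor206,
        )
        for row in df.itertuples()
    ]


def write_motif_table(panel: Iterable[MotifSet], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "variant_id": m.variant_id,
                "motif1": m.motif1,
                "motif2": m.motif2,
                "motif3": m.motif3,
                "anchor206": m.anchor206,
            }
            for m in panel
        ]
    ).to_csv(path, sep="\t", index=False)
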