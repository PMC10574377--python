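"""Dataset curation: measurement window, stereo-aware deduplication,
model-based anomaly flagging.

The rules mirror how a refractive-index training base is prepared:

* measurements must come from the 20–30 °C window (at 589 nm); records
  with a known temperature outside it are dropped;
* enantiomers share their physical properties, so a pair of mirror-image
  records and their racemate collapse onto a single survivor (a
  stereo-labeled enantiomer is preferred over the racemate);
* an E/Z- or cis/trans-unspecified *mixture* has no well-defined
  composition: it is dropped whenever a pure stereoisomer of the same
  skeleton is present, but kept (unlabeled) when it stands alone;
* once a model is trained, records whose prediction deviates from the
  measurement by more than 0.020 in absolute value are flagged for manual
  literature verification — flagged, never auto-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import chem_graph as cg

ANOMALY_THRESHOLD = 0.020

KEPT = "kept"
STATUS_VALUES = (
    KEPT, "duplicate", "racemate_dropped", "mixture_dropped",
    "window_dropped", "replaced", "quarantined",
)


@dataclass
class CompoundRecord:
    """One dataset row: SMILES, measured RI (3 decimals) and bookkeeping."""

    smiles: str
    ri: float
    temperature: Optional[float] = None
    id: str = ""
    status: str = KEPT
    reason: str = ""

    def __post_init__(self) -> None:
        self.ri = round(float(self.ri), 3)  # values carry 3 decimals

    @property
    def kept(self) -> bool:
        return self.status == KEPT


@dataclass
class AnomalyFlag:
    """Deviation of a model prediction from the measured value."""

    record_id: str
    measured: float
    predicted: Optional[float]
    deviation: Optional[float]
    flagged: bool
    error: str = ""


def filter_measurement_window(
    records: Sequence[CompoundRecord],
    t_low: float = 20.0,
    t_high: float = 30.0,
) -> list[CompoundRecord]:
    """Drop records measured outside the temperature window.

    Records with no recorded temperature are kept (catalog sources often
    omit it; the reference conditions are then assumed).
    """
    out = []
    for rec in records:
        if not rec.kept:
            out.append(rec)
            continue
        if rec.temperature is not None and not (
            t_low <= rec.temperature <= t_high
        ):
            out.append(
                replace(
                    rec,
                    status="window_dropped",
                    reason=f"measured at {rec.temperature:g} °C",
                )
            )
        else:
            out.append(rec)
    return out


def _encode_keys(rec: CompoundRecord, alphabet) -> tuple[str, str, bool]:
    """(full key, stereo-free key, had stereo labels in the input)."""
    graph = cg.assign_stereo_labels(cg.parse_smiles(rec.smiles, alphabet))
    has_stereo_input = any(n.stereo_labels for n in graph.nodes)
    stripped = cg.strip_single_stereocenter(graph)
    full = cg.canonical_serialization(cg.to_rooted_dag(stripped))
    bare = cg.canonical_serialization(
        cg.to_rooted_dag(cg.parse_smiles(rec.smiles, alphabet))
    )
    return full, bare, has_stereo_input


def deduplicate_stereo(
    records: Sequence[CompoundRecord],
    alphabet: Sequence[str] = cg.DEFAULT_ALPHABET,
) -> list[CompoundRecord]:
    """Collapse enantiomer/racemate duplicates and drop stereo mixtures.

    Records are keyed by the canonical serialization of their labeled DAG
    after single-stereocentre stripping, so both enantiomers and their
    racemate collide while diastereomers stay distinct.  Within a colliding
    group the survivor prefers a record whose input SMILES carried stereo
    labels, ties broken by lexicographically smallest SMILES.  A record
    without stereo labels whose skeleton also occurs with labels is an
    unspecified mixture and is dropped; mixtures standing alone are kept.
    Unparseable SMILES are quarantined with the parse error as reason.
    """
    keyed: list[tuple[CompoundRecord, Optional[tuple[str, str, bool]]]] = []
    for rec in records:
        if not rec.kept:
            keyed.append((rec, None))
            continue
        try:
            keyed.append((rec, _encode_keys(rec, alphabet)))
        except (cg.SmilesError, cg.DisconnectedGraphError, ValueError) as exc:
            keyed.append(
                (replace(rec, status="quarantined", reason=str(exc)), None)
            )

    # group kept records by full key
    groups: dict[str, list[int]] = {}
    for i, (rec, keys) in enumerate(keyed):
        if keys is not None and rec.kept:
            groups.setdefault(keys[0], []).append(i)

    out = [rec for rec, _ in keyed]
    survivors: list[int] = []
    for full_key, idxs in groups.items():
        if len(idxs) == 1:
            survivors.append(idxs[0])
            continue
        winner = min(
            idxs,
            key=lambda i: (not keyed[i][1][2], keyed[i][0].smiles),
        )
        survivors.append(winner)
        for i in idxs:
            if i == winner:
                continue
            loser, keys = keyed[i]
            status = (
                "racemate_dropped"
                if (not keys[2]) and keyed[winner][1][2]
                else "duplicate"
            )
            out[i] = replace(
                out[i],
                status=status,
                reason=f"same graph machine as {keyed[winner][0].smiles!r}",
            )

    # mixture rule on the survivors: group by stereo-free key
    bare_groups: dict[str, list[int]] = {}
    for i in survivors:
        bare_groups.setdefault(keyed[i][1][1], []).append(i)
    for bare_key, idxs in bare_groups.items():
        if len(idxs) < 2:
            continue
        labeled = [i for i in idxs if keyed[i][1][2]]
        if not labeled:
            continue
        for i in idxs:
            if not keyed[i][1][2]:
                out[i] = replace(
                    out[i],
                    status="mixture_dropped",
                    reason="unspecified stereo mixture; pure isomer present",
                )
    return out


def flag_anomalies(
    records: Sequence[CompoundRecord],
    predictor: Union[Callable[[str], float], Sequence[float]],
    threshold: float = ANOMALY_THRESHOLD,
) -> list[AnomalyFlag]:
    """Flag records whose |predicted − measured| exceeds the threshold.

    ``predictor`` is either a callable mapping SMILES to a predicted RI or
    a sequence of predictions aligned with ``records``.  Flagged records
    are meant for manual literature verification; nothing is modified.
    """
    flags = []
    for i, rec in enumerate(records):
        try:
            pred = (
                float(predictor[i])
                if not callable(predictor)
                else float(predictor(rec.smiles))
            )
        except Exception as exc:  # prediction failure becomes an error flag
            flags.append(
                AnomalyFlag(
                    record_id=rec.id or rec.smiles,
                    measured=rec.ri,
                    predicted=None,
                    deviation=None,
                    flagged=False,
                    error=str(exc),
                )
            )
            continue
        dev = round(pred - rec.ri, 3)
        flags.append(
            AnomalyFlag(
                record_id=rec.id or rec.smiles,
                measured=rec.ri,
                predicted=pred,
                deviation=dev,
                flagged=bool(abs(dev) > threshold),
            )
        )
    return flags


def curation_report(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Tabular report of every record with its status and reason."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "ri": [r.ri for r in records],
            "temperature": [r.temperature for r in records],
            "status": [r.status for r in records],
            "reason": [r.reason for r in records],
        }
    )
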