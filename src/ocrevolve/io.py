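"""Serialisation: FASTA clone sets, TSV libraries/reports, YAML configs."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import DEFAULT_THRESHOLDS, RuleThresholds, classify_clone
from .isor import Library, _ARTIFACT_CODE, _CODE_ARTIFACT
from .scaffold import (Artifact, ChargeState, ReferenceScaffold,
                       charge_profile, charge_state, scaffold_to_config)


def write_clones_fasta(states: Iterable[ChargeState], path: str | Path,
                       ) -> int:
    """Write clone sequences as protein FASTA; the artifact class goes in
    the description line.  Empty-vector clones (no sequence) are skipped."""
    records = []
    for s in states:
        if s.artifact is Artifact.EMPTY_VECTOR:
            continue
        records.append(SeqRecord(Seq(s.sequence()), id=s.clone_id or "clone",
                                 description=f"artifact={s.artifact.value}"))
    return SeqIO.write(records, str(path), "fasta")


def read_clones_fasta(path: str | Path, scaffold: ReferenceScaffold
                      ) -> list[ChargeState]:
    states = []
    for rec in SeqIO.parse(str(path), "fasta"):
        states.append(charge_state(str(rec.seq), scaffold, clone_id=rec.id))
    return states


# ---------------------------------------------------------------------------
# Library TSV (compact: one clone per row, acidic positions as a list)
# ---------------------------------------------------------------------------


def write_library_tsv(library: Library, path: str | Path) -> None:
    rows = []
    for i in range(len(library)):
        positions = ",".join(
            str(p) for p, a in zip(library.scaffold.chargeable_positions,
                                   library.acidic[i]) if a)
        rows.append({
            "clone_id": f"r{library.round_index}_{i}",
            "acidic_positions": positions or "-",
            "artifact": _CODE_ARTIFACT[int(library.artifact[i])].value,
            "round": library.round_index,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_library_tsv(path: str | Path,
                     scaffold: ReferenceScaffold) -> Library:
    df = pd.read_csv(path, sep="\t", dtype=str)
    n = len(df)
    acidic = np.zeros((n, scaffold.n_chargeable), dtype=bool)
    artifact = np.zeros(n, dtype=np.uint8)
    idx = scaffold.position_index
    for i, row in enumerate(df.itertuples(index=False)):
        if row.acidic_positions != "-":
            for tok in str(row.acidic_positions).split(","):
                acidic[i, idx[int(tok)]] = True
        artifact[i] = _ARTIFACT_CODE[Artifact(row.artifact)]
    round_index = int(df["round"].iloc[0]) if n else 0
    return Library(scaffold, acidic, artifact, round_index=round_index)


# ---------------------------------------------------------------------------
# Classification report
# ---------------------------------------------------------------------------


def classification_table(states: Sequence[ChargeState],
                         thresholds: RuleThresholds = DEFAULT_THRESHOLDS
                         ) -> pd.DataFrame:
    """One row per clone: counts, pI, phenotype and per-condition trace."""
    rows = []
    for s in states:
        call = classify_clone(s, thresholds)
        row: dict[str, object] = {"clone_id": s.clone_id,
                                  "artifact": s.artifact.value}
        if s.artifact is Artifact.INTACT:
            p = charge_profile(s)
            row.update(total=p.total, central=p.central,
                       specific=p.specific, flanking=p.flanking,
                       loop1=p.loop1, loop2=p.loop2,
                       flanking_pct=(round(p.flanking_pct, 2)
                                     if p.flanking_pct is not None
                                     else None),
                       pI=round(call.pI_value, 3))
        row["phenotype"] = call.phenotype.value
        for cond, ok in call.trace.items():
            row[f"pass_{cond}"] = ok
        rows.append(row)
    return pd.DataFrame(rows)


def write_classification_tsv(states: Sequence[ChargeState],
                             path: str | Path,
                             thresholds: RuleThresholds = DEFAULT_THRESHOLDS
                             ) -> None:
    classification_table(states, thresholds).to_csv(path, sep="\t",
                                                    index=False)


# ---------------------------------------------------------------------------
# Labelled variant sets
# ---------------------------------------------------------------------------


def write_variant_set_tsv(variant_set, path: str | Path) -> None:
    rows = []
    for state, label in variant_set.entries:
        positions = ",".join(str(p) for p in state.acidic_positions)
        rows.append({"clone_id": state.clone_id, "label": label,
                     "acidic_positions": positions or "-"})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_variant_set_tsv(path: str | Path, scaffold: ReferenceScaffold):
    from .analytics import LabelledVariantSet

    df = pd.read_csv(path, sep="\t", dtype=str)
    idx = scaffold.position_index
    entries = []
    for row in df.itertuples(index=False):
        acidic = np.zeros(scaffold.n_chargeable, dtype=bool)
        if row.acidic_positions != "-":
            for tok in str(row.acidic_positions).split(","):
                acidic[idx[int(tok)]] = True
        entries.append((ChargeState(scaffold, acidic,
                                    clone_id=str(row.clone_id)),
                        str(row.label)))
    return LabelledVariantSet(entries=entries, source=str(path))


# ---------------------------------------------------------------------------
# Scaffold config
# ---------------------------------------------------------------------------


def write_scaffold(scaffold: ReferenceScaffold, fasta_path: str | Path,
                   config_path: str | Path) -> None:
    record = SeqRecord(Seq(scaffold.sequence), id=scaffold.name,
                       description="synthetic charge-annotated scaffold")
    SeqIO.write([record], str(fasta_path), "fasta")
    with open(config_path, "w") as fh:
        yaml.safe_dump(scaffold_to_config(scaffold), fh, sort_keys=False)
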