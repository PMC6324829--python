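"""Readers and writers: FASTA + BED pair datasets, simulation bundles, results.

Conventions:

* paired FASTA files carry one record per region, matched across species by
  identical record ids;
* peak intervals come as region-relative BED (0-based, half-open, with the
  chrom field holding the region id); every base covered by at least one
  interval is state 1;
* results go to a TSV with one row per region (floats at 6 significant
  digits, rows ordered by id) that round-trips through the companion reader.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .likelihood import HomologousPair, MarkTrack, ModelKind
from .regions import RegionReport, RegionLikelihoods
from .simulate import SimulatedPair

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["id", "sA", "sB", "logL_N", "logL_M", "logL_I", "logL_B",
                  "best_model", "r_ind", "r_mut", "r_ind_len", "r_mut_len"]


class PairedInputError(ValueError):
    """FASTA/BED inputs are inconsistent."""


def _read_fasta_map(path: str | Path) -> dict[str, str]:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise PairedInputError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise PairedInputError(f"{path}: no FASTA records")
    return records


def _read_bed_intervals(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Region-relative BED: chrom (= region id), start, end; extra cols ignored."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["region", "start", "end"],
                         dtype={"region": str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise PairedInputError(f"{path}: malformed BED: {exc}") from None
    out: dict[str, list[tuple[int, int]]] = {}
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError):
            raise PairedInputError(
                f"{path}: line {line_no}: non-integer coordinates") from None
        if start < 0 or end < start:
            raise PairedInputError(
                f"{path}: line {line_no}: invalid interval [{start}, {end})")
        out.setdefault(row.region, []).append((start, end))
    return out


def _binarize(length: int, intervals: list[tuple[int, int]],
              region_id: str, source: str) -> np.ndarray:
    track = np.zeros(length, dtype=np.int8)
    for start, end in intervals:
        if end > length:
            warnings.warn(
                f"{source}: interval [{start}, {end}) on {region_id} exceeds "
                f"region length {length}; clipping", stacklevel=2)
            end = length
        if start >= length:
            continue
        track[start:end] = 1  # union of possibly overlapping intervals
    return track


def read_pair_dataset(fastaA: str | Path, fastaB: str | Path,
                      bed_sources: list[tuple[str | Path, str | Path]],
                      ) -> list[HomologousPair]:
    """Assemble homologous pairs from paired FASTA plus per-mark BED files.

    ``bed_sources`` lists one (bedA, bedB) tuple per mark, in mark order.
    Regions with no BED line get an all-zero track.
    """
    seqsA = _read_fasta_map(fastaA)
    seqsB = _read_fasta_map(fastaB)
    only_a = sorted(set(seqsA) - set(seqsB))
    only_b = sorted(set(seqsB) - set(seqsA))
    if only_a or only_b:
        raise PairedInputError(
            f"unpaired region ids: only in {fastaA}: {only_a}; "
            f"only in {fastaB}: {only_b}")
    beds = [(_read_bed_intervals(ba), _read_bed_intervals(bb), str(ba), str(bb))
            for ba, bb in bed_sources]
    pairs = []
    for rid in sorted(seqsA):
        seqA, seqB = seqsA[rid], seqsB[rid]
        tracksA, tracksB = [], []
        for h, (bedA, bedB, nameA, nameB) in enumerate(beds, start=1):
            tracksA.append(MarkTrack(h, _binarize(
                len(seqA), bedA.get(rid, []), rid, nameA)))
            tracksB.append(MarkTrack(h, _binarize(
                len(seqB), bedB.get(rid, []), rid, nameB)))
        pairs.append(HomologousPair(rid, seqA, seqB,
                                    tuple(tracksA), tuple(tracksB)))
    return pairs


# ---------------------------------------------------------------------------
# simulation bundles
# ---------------------------------------------------------------------------

def write_simulation_bundle(sims: list[SimulatedPair], manifest: dict,
                            outdir: str | Path) -> dict[str, Path]:
    """Write FASTA x2, per-mark/per-species BED, and the manifest JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for side in ("A", "B"):
        recs = []
        for s in sims:
            seq = s.pair.seqA if side == "A" else s.pair.seqB
            recs.append(SeqRecord(Seq(seq), id=s.pair.identifier,
                                  description=""))
        paths[f"fasta{side}"] = out / f"species{side}.fasta"
        SeqIO.write(recs, str(paths[f"fasta{side}"]), "fasta")
    H = sims[0].pair.n_marks
    for h in range(1, H + 1):
        for side in ("A", "B"):
            lines = []
            for s in sims:
                tracks = s.pair.tracksA if side == "A" else s.pair.tracksB
                states = tracks[h - 1].states
                # runs of 1s -> half-open intervals
                padded = np.concatenate([[0], states, [0]])
                diff = np.diff(padded)
                starts = np.nonzero(diff == 1)[0]
                ends = np.nonzero(diff == -1)[0]
                for st, en in zip(starts, ends):
                    lines.append(f"{s.pair.identifier}\t{st}\t{en}")
            key = f"bed_mark{h}_{side}"
            paths[key] = out / f"mark{h}.species{side}.bed"
            paths[key].write_text("\n".join(lines) + ("\n" if lines else ""))
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=1) + "\n")
    return paths


def read_simulation_bundle(bundle_dir: str | Path) -> list[HomologousPair]:
    """Read back a bundle written by :func:`write_simulation_bundle`."""
    d = Path(bundle_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    H = len(manifest["pi1"])
    bed_sources = [(d / f"mark{h}.speciesA.bed", d / f"mark{h}.speciesB.bed")
                   for h in range(1, H + 1)]
    return read_pair_dataset(d / "speciesA.fasta", d / "speciesB.fasta",
                             bed_sources)


# ---------------------------------------------------------------------------
# results table
# ---------------------------------------------------------------------------

def _fmt(value: float | None) -> str:
    return "NA" if value is None else format(value, ".6g")


def write_results_tsv(reports: list[RegionReport], path: str | Path) -> None:
    """One row per region, deterministic order by id; NA for undefined."""
    rows = []
    for rep in sorted(reports, key=lambda r: r.identifier):
        rl = rep.likelihoods
        rows.append("\t".join([
            rl.identifier, str(rl.sA), str(rl.sB),
            _fmt(rl.logL[ModelKind.N]), _fmt(rl.logL[ModelKind.M]),
            _fmt(rl.logL[ModelKind.I]), _fmt(rl.logL[ModelKind.B]),
            rep.best_model.name,
            _fmt(rep.r_ind), _fmt(rep.r_mut),
            _fmt(rep.r_ind_len), _fmt(rep.r_mut_len),
        ]))
    Path(path).write_text(
        "\t".join(RESULT_COLUMNS) + "\n" + "".join(r + "\n" for r in rows))


def read_results_tsv(path: str | Path) -> list[RegionReport]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str}, na_values=["NA"],
                     keep_default_na=False)
    if list(df.columns) != RESULT_COLUMNS:
        raise PairedInputError(f"{path}: unexpected results columns")
    out = []
    for row in df.itertuples(index=False):
        rl = RegionLikelihoods(
            identifier=row.id,
            logL={ModelKind.N: float(row.logL_N), ModelKind.M: float(row.logL_M),
                  ModelKind.I: float(row.logL_I), ModelKind.B: float(row.logL_B)},
            sA=int(row.sA), sB=int(row.sB))
        out.append(RegionReport(
            likelihoods=rl,
            best_model=ModelKind[row.best_model],
            r_ind=None if pd.isna(row.r_ind) else float(row.r_ind),
            r_mut=None if pd.isna(row.r_mut) else float(row.r_mut),
            r_ind_len=float(row.r_ind_len),
            r_mut_len=float(row.r_mut_len)))
    return out
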