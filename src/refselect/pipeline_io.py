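"""End-to-end driver: sequence I/O, reference selection, reordering, report.

Input is FASTA or one-sequence-per-line text.  The driver builds the
candidate-count table, computes the similarity matrix, selects k reference
sequences (Markov clustering by default, exhaustive enumeration on request)
and returns the dataset with the selected sequences moved to the front —
selected ones in ascending original index, the rest in original relative
order — plus a JSON-serializable run report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .clustering import (
    MCLConfig,
    exhaustive_select,
    mcl_cluster,
    refine_cluster,
    select_references,
)
from .motif_math import PMSParams, build_count_table
from .pairwise import (
    DNA_ALPHABET,
    SequenceSet,
    similarity_matrix,
    total_candidate_count,
)

__all__ = [
    "RunConfig",
    "read_sequences",
    "write_sequences",
    "run_refselect",
    "write_outputs",
]

logger = logging.getLogger("refselect")


@dataclass
class RunConfig:
    """Configuration for one selection run.

    Exactly one of ``k`` or the pair ``(q, h)`` must be given; in the latter
    case ``k = t - q + h`` is derived at run time.
    """

    l: int
    d: int
    k: int | None = None
    q: int | None = None
    h: int | None = None
    alphabet: str = "auto"
    workers: int = 1
    mode: str = "cluster"
    mcl: MCLConfig = field(default_factory=MCLConfig)

    def __post_init__(self) -> None:
        has_k = self.k is not None
        has_qh = self.q is not None or self.h is not None
        if has_k == has_qh or (has_qh and (self.q is None or self.h is None)):
            raise ValueError("provide exactly one of k or the pair (q, h)")
        if self.mode not in ("cluster", "exhaustive"):
            raise ValueError(f"mode must be 'cluster' or 'exhaustive', got {self.mode!r}")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")

    def resolve_k(self, t: int) -> int:
        k = self.k if self.k is not None else t - self.q + self.h
        if not 1 < k < t:
            raise ValueError(f"derived k={k} must satisfy 1 < k < t (t={t})")
        return k


def _detect_alphabet(sequences: list[str]) -> str:
    chars = set("".join(sequences))
    return "dna" if chars <= set(DNA_ALPHABET) else "protein"


def read_sequences(path, format: str = "auto", alphabet: str = "auto") -> SequenceSet:
    """Read a FASTA or line-per-sequence file into a validated SequenceSet.

    Sequences are uppercased; alphabet 'auto' resolves to DNA iff every
    character is one of ACGT, protein otherwise.  Unequal lengths or
    characters outside the declared alphabet raise with the record name.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty input file")
    if format == "auto":
        format = "fasta" if text.lstrip().startswith(">") else "lines"

    sequences: list[str] = []
    identifiers: list[str] = []
    if format == "fasta":
        for record in SeqIO.parse(str(path), "fasta"):
            identifiers.append(record.description or record.id)
            sequences.append(str(record.seq).upper())
        if not sequences:
            raise ValueError(f"{path}: no FASTA records found")
    elif format == "lines":
        for i, line in enumerate(text.splitlines()):
            line = line.strip()
            if line:
                identifiers.append(f"seq{len(sequences) + 1}")
                sequences.append(line.upper())
    else:
        raise ValueError(f"unknown format {format!r}")

    if alphabet == "auto":
        alphabet = _detect_alphabet(sequences)
    return SequenceSet(sequences=sequences, identifiers=identifiers, alphabet=alphabet)


def write_sequences(data: SequenceSet, path, format: str = "fasta") -> None:
    """Write sequences as single-line FASTA or plain lines."""
    path = Path(path)
    if format == "fasta":
        with path.open("w") as fh:
            for ident, seq in zip(data.identifiers, data.sequences):
                fh.write(f">{ident}\n{seq}\n")
    elif format == "lines":
        path.write_text("".join(f"{seq}\n" for seq in data.sequences))
    else:
        raise ValueError(f"unknown format {format!r}")


def run_refselect(data: SequenceSet, config: RunConfig) -> tuple[SequenceSet, dict]:
    """Select k reference sequences and prepose them in the dataset.

    Returns the reordered SequenceSet and a report dict with the selection,
    per-stage timings, candidate-count totals for the selected and the
    first-k sets, and cluster diagnostics (cluster mode only).
    """
    t = data.t
    k = config.resolve_k(t)
    alphabet = data.alphabet
    params = PMSParams(l=config.l, d=config.d, sigma=data.sigma, n=data.n)

    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    table = build_count_table(params)
    timings["count_table"] = time.perf_counter() - t0
    logger.info("count table built for l=%d d=%d sigma=%d", params.l, params.d, params.sigma)

    t0 = time.perf_counter()
    matrix = similarity_matrix(data, params, workers=config.workers, table=table)
    timings["similarity_matrix"] = time.perf_counter() - t0
    logger.info("similarity matrix for t=%d sequences (%.2fs)", t, timings["similarity_matrix"])

    diagnostics: dict = {}
    warnings_list: list[str] = []
    t0 = time.perf_counter()
    if config.mode == "exhaustive":
        chosen = exhaustive_select(matrix, k)
    else:
        clusters = mcl_cluster(matrix, config.mcl)
        if not clusters.converged:
            warnings_list.append("MCL did not converge within max_iterations")
        refinements = []
        for c in clusters.clusters:
            rs = refine_cluster(c, k, matrix)
            refinements.append(
                {
                    "members": c,
                    "valid": len(c) > 1,
                    "case": rs.provenance if rs else "invalid",
                    "score": rs.score if rs else None,
                }
            )
        diagnostics["clusters"] = refinements
        chosen = select_references(matrix, k, config.mcl)
    timings["selection"] = time.perf_counter() - t0

    selected = chosen.indices
    first_k = list(range(k))
    n_improved = total_candidate_count(selected, matrix)
    n_original = total_candidate_count(first_k, matrix)
    ratio = float("inf") if n_improved == 0 else n_original / n_improved

    order = selected + [i for i in range(t) if i not in set(selected)]
    reordered = SequenceSet(
        sequences=[data.sequences[i] for i in order],
        identifiers=[data.identifiers[i] for i in order],
        alphabet=alphabet,
    )

    report = {
        "input": {"t": t, "n": data.n, "alphabet": alphabet},
        "params": {"l": config.l, "d": config.d, "k": k, "mode": config.mode,
                   "workers": config.workers},
        "selected_indices": selected,
        "selected_identifiers": [data.identifiers[i] for i in selected],
        "score": chosen.score,
        "provenance": chosen.provenance,
        "n_selected": n_improved,
        "n_first_k": n_original,
        "ratio_original_over_improved": ratio,
        "timings": timings,
        "diagnostics": diagnostics,
        "warnings": warnings_list,
    }
    return reordered, report


def write_outputs(
    data: SequenceSet,
    report: dict,
    out_path,
    report_path,
    format: str = "fasta",
) -> None:
    """Write the reordered sequences and the JSON report."""
    write_sequences(data, out_path, format=format)
    Path(report_path).write_text(json.dumps(_jsonable(report), indent=2) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {key: _jsonable(val) for key, val in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(val) for val in obj]
    if isinstance(obj, float) and obj == float("inf"):
        return "inf"
    if hasattr(obj, "item"):
        return obj.item()
    return obj
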