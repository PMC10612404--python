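"""Shared helpers: run the hermetic pipeline (ledger -> PAF -> parse -> eval)."""

from __future__ import annotations

from ecbench import (
    evaluate_read,
    pair_reads,
    parse_alignments,
    summarize,
)
from ecbench.synthetic import Simulation, emit_truth_alignments


def eval_sim(sim: Simulation, tmp_path, **eval_kwargs):
    """Emit truth PAFs for a simulation, parse them back, pair and evaluate.

    Returns (pairing, evals, summary)."""
    tmp_path.mkdir(parents=True, exist_ok=True)
    raw_paf = tmp_path / "raw.paf"
    corr_paf = tmp_path / "corr.paf"
    emit_truth_alignments(sim, "raw", raw_paf)
    emit_truth_alignments(sim, "corrected", corr_paf)
    raws = list(parse_alignments(raw_paf))
    corrs = list(parse_alignments(corr_paf))
    pairing = pair_reads(raws, corrs)
    evals = [evaluate_read(r, c, **eval_kwargs) for r, c in pairing.pairs]
    return pairing, evals, summarize(evals)
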