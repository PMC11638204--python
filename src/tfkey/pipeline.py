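"""End-to-end orchestration: expression matrix → ranked gene lists → per-
(TF set, sample) weighted-tau tests → FDR → signed-score matrix.

Each result row carries the two-sided p, the Benjamini–Hochberg q (computed
within each sample across TFs by default), the direction of association and
the signed score sign(τ)·(−log10 p) used to profile TF activity across
samples. Pairs whose gene overlap falls below ``min_overlap`` are kept as
NA rows so the score-matrix shape is stable.

:func:`make_fixture` writes a small, fully synthetic but format-faithful
input bundle (expression TSV, promoter FASTA, JASPAR PWMs, ranked gene-set
TSV and a JSON manifest) with optional planted (TF, sample) associations,
for testing and demonstration.
"""

from __future__ import annotations

import json
import os
import time
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as tfio
from .expr_index import (ExpressionMatrix, LIST_METHODS, build_star_layout,
                         ed_scores, ee_scores, pem_scores, spm_scores,
                         start_scores)
from .rankcorr import align_ranks, normalize_scheme, association_test

__all__ = ["fdr_bh", "signed_score", "run_pipeline", "make_fixture",
           "score_matrix_for_method"]

#: −log10(p) values are capped here to avoid infinities from underflowed p
SIGNED_SCORE_CAP = 300.0


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotonicity enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def signed_score(direction: int, p: float, cap: float = SIGNED_SCORE_CAP) -> float:
    """sign(τ) · min(−log10 p, cap)."""
    with np.errstate(divide="ignore"):
        neglog = -np.log10(p)
    return float(direction) * min(neglog, cap)


def score_matrix_for_method(matrix: ExpressionMatrix, method: str,
                            pseudo: float = 1e-3,
                            normalize: bool = False) -> pd.DataFrame:
    """Genes x samples rank-score matrix for one gene-list method."""
    method = method.lower()
    if method not in LIST_METHODS:
        raise ValueError(
            f"{method!r} is not a gene-list builder (choose from {LIST_METHODS})"
        )
    if method == "ed":
        return ed_scores(matrix)
    if method == "pem":
        return pem_scores(matrix, pseudo=pseudo)
    if method == "spm":
        return spm_scores(matrix)
    if method == "ee":
        return ee_scores(matrix, pseudo=pseudo)
    return start_scores(matrix, layout=build_star_layout(matrix),
                        normalize=normalize)


def run_pipeline(
    matrix: ExpressionMatrix,
    gene_sets: Mapping[str, Mapping[str, float]],
    index_method: str = "ed",
    scheme=7,
    fdr: float = 0.05,
    min_overlap: int = 10,
    pseudo: float = 1e-3,
    fdr_scope: str = "sample",
    null: str = "asymptotic",
    n_perm: int = 999,
    seed: int = 0,
    normalize: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Test every (gene set, sample) pair and assemble the signed-score matrix.

    Returns ``(results, scores, info)``: the tidy result table (one row per
    pair, NA columns for untestable pairs), the TF x sample signed-score
    matrix, and a run-info dict (counts, timings, options) suitable for a
    JSON sidecar.
    """
    t0 = time.perf_counter()
    scheme = normalize_scheme(scheme)
    if fdr_scope not in ("sample", "global"):
        raise ValueError("fdr_scope must be 'sample' or 'global'")
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    set_ids = sorted(str(s) for s in gene_sets)
    matrix_genes = set(matrix.gene_ids)
    union = set()
    for members in gene_sets.values():
        union.update(str(g) for g in members)
    if not union & matrix_genes:
        raise ValueError(
            f"no genes shared between the expression matrix ({len(matrix_genes)} "
            f"genes) and any gene set ({len(union)} genes) — check id spaces"
        )
    lists = score_matrix_for_method(matrix, index_method, pseudo=pseudo,
                                    normalize=normalize)
    rows = []
    n_untestable = 0
    for sample in matrix.sample_ids:
        gene_list = lists[sample]
        for set_id in set_ids:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                pairs = align_ranks(gene_sets[set_id], gene_list,
                                    min_overlap=min_overlap)
            if not pairs.testable:
                n_untestable += 1
                rows.append({"set_id": set_id, "sample_id": sample,
                             "n_overlap": pairs.n, "tau": np.nan, "z": np.nan,
                             "p": np.nan, "q": np.nan, "direction": np.nan,
                             "signed_score": np.nan})
                continue
            res = association_test(pairs, scheme, null=null, n_perm=n_perm,
                                   seed=seed)
            rows.append({"set_id": set_id, "sample_id": sample,
                         "n_overlap": res.n_overlap, "tau": res.tau,
                         "z": res.z, "p": res.p, "q": np.nan,
                         "direction": res.direction,
                         "signed_score": signed_score(res.direction, res.p)})
    results = pd.DataFrame(rows, columns=tfio.RESULT_COLUMNS)
    tested = results["p"].notna()
    if tested.any():
        if fdr_scope == "sample":
            for sample in matrix.sample_ids:
                sel = tested & (results["sample_id"] == sample)
                if sel.any():
                    results.loc[sel, "q"] = fdr_bh(results.loc[sel, "p"])
        else:
            results.loc[tested, "q"] = fdr_bh(results.loc[tested, "p"])
    scores = results.pivot(index="set_id", columns="sample_id",
                           values="signed_score")
    scores = scores.reindex(index=set_ids, columns=list(matrix.sample_ids))
    scores.columns.name = None
    scores.index.name = "set_id"
    info = {
        "index_method": index_method,
        "scheme": scheme,
        "fdr": fdr,
        "fdr_scope": fdr_scope,
        "min_overlap": min_overlap,
        "null": null,
        "seed": seed,
        "n_sets": len(set_ids),
        "n_samples": int(matrix.n_samples),
        "n_genes": int(len(matrix.gene_ids)),
        "n_pairs": int(len(results)),
        "n_untestable": n_untestable,
        "n_significant": int((results["q"] < fdr).sum()),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    return results, scores, info


# ---------------------------------------------------------------------------
# synthetic fixture
# ---------------------------------------------------------------------------

def _write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def _write_jaspar(counts_by_tf: Mapping[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for k, (tf, counts) in enumerate(sorted(counts_by_tf.items()), start=1):
            fh.write(f">M{k:04d} {tf}\n")
            for base, row in zip("ACGT", counts):
                fh.write(f"{base} [ " + " ".join(str(int(c)) for c in row)
                         + " ]\n")


def make_fixture(
    out_dir,
    seed: int = 42,
    n_genes: int = 200,
    n_samples: int = 5,
    n_tfs: int = 3,
    planted: Sequence[tuple[int, int, float]] = (),
    member_fraction: float = 0.6,
    promoter_length: int = 120,
    motif_width: int = 8,
) -> dict:
    """Write a coherent synthetic input bundle and return its manifest.

    ``planted`` lists (tf_index, sample_index, rho) triples: that TF's member
    rank scores are drawn with correlation ``rho`` against the ED scores of
    the indicated sample, so the pipeline should recover the association.
    All other sets carry scores independent of every gene list. Byte-level
    reproducible for a given seed.
    """
    if n_genes < 50:
        raise ValueError("n_genes must be at least 50")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    samples = [f"S{j}" for j in range(1, n_samples + 1)]
    tfs = [f"TF{k:02d}" for k in range(1, n_tfs + 1)]

    # TPM-like expression: log-normal baseline with per-gene/sample jitter
    expr = rng.lognormal(mean=1.0, sigma=1.0, size=(n_genes, n_samples))
    frame = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"),
                         columns=samples)
    matrix = ExpressionMatrix.from_frame(frame)
    ed = ed_scores(matrix)

    planted_records = []
    sets: dict[str, dict[str, float]] = {}
    n_members = max(int(round(member_fraction * n_genes)), 10)
    planted_by_tf = {int(t): (int(s), float(r)) for t, s, r in planted}
    for k, tf in enumerate(tfs):
        members = sorted(rng.choice(genes, size=n_members, replace=False))
        if k in planted_by_tf:
            s_idx, rho = planted_by_tf[k]
            target = ed[samples[s_idx]].loc[members].to_numpy()
            zt = (target - target.mean()) / target.std()
            scores = rho * zt + np.sqrt(1.0 - rho * rho) * rng.standard_normal(
                len(members))
            planted_records.append({"set_id": tf, "sample_id": samples[s_idx],
                                    "rho": rho})
        else:
            scores = rng.standard_normal(len(members))
        sets[tf] = dict(zip(members, np.round(scores, 6)))

    promoters = ["".join(rng.choice(list("ACGT"), size=promoter_length))
                 for _ in genes]
    # sharply peaked count matrices (consensus base dominates each column)
    # so that implanted consensus sites score above the usual threshold
    pwm_counts = {}
    for tf in tfs:
        counts = rng.integers(1, 5, size=(4, motif_width))
        cons = rng.integers(0, 4, size=motif_width)
        counts[cons, np.arange(motif_width)] += 40
        pwm_counts[tf] = counts
    # implant each TF's consensus into ~30% of promoters so scanning the
    # bundle yields sites
    for tf in tfs:
        consensus = "".join("ACGT"[b] for b in pwm_counts[tf].argmax(axis=0))
        carriers = rng.choice(n_genes, size=max(n_genes // 3, 1),
                              replace=False)
        for gi in carriers:
            pos = int(rng.integers(0, promoter_length - motif_width + 1))
            seq = promoters[gi]
            promoters[gi] = seq[:pos] + consensus + seq[pos + motif_width:]

    tfio.write_expression(frame, os.path.join(out_dir, "expression.tsv"))
    _write_fasta(list(zip(genes, promoters)),
                 os.path.join(out_dir, "promoters.fasta"))
    _write_jaspar(pwm_counts, os.path.join(out_dir, "pwms.jaspar"))
    tfio.write_gene_sets(sets, os.path.join(out_dir, "gene_sets.tsv"))
    manifest = {
        "seed": int(seed),
        "n_genes": int(n_genes),
        "n_samples": int(n_samples),
        "n_tfs": int(n_tfs),
        "member_fraction": member_fraction,
        "planted": planted_records,
        "files": ["expression.tsv", "promoters.fasta", "pwms.jaspar",
                  "gene_sets.tsv"],
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
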