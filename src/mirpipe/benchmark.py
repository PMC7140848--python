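"""Score a pipeline run against the synthetic answer key.

Used by the acceptance checks: recovery of planted differential expression
(direction and genotype membership), recovery of planted novel hairpins,
false-positive rate among non-planted candidates, and the multinomial
z-scores of the recovered structural-RNA class fractions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simdata import SimConfig, TruthTable


def _novel_name_map(novel_calls: pd.DataFrame, truth: TruthTable) -> dict[str, str]:
    """Pipeline novel id -> truth name, joined on the mature sequence."""
    seq_to_truth = {truth.mature_seqs[n]: n for n in truth.mature_seqs
                    if n.startswith("nov")}
    out = {}
    for _, row in novel_calls.iterrows():
        if row["novel_id"] and row["sequence"] in seq_to_truth:
            out[row["novel_id"]] = seq_to_truth[row["sequence"]]
    return out


def de_recovery(bundle: dict, truth: TruthTable,
                min_mean_count: float = 50.0,
                strong_lfc: float = 2.0) -> dict:
    """Fraction of planted strong-DE miRNAs recovered with the correct
    direction and genotype-membership label.

    Strong-DE = planted |log2FC| >= ``strong_lfc`` (infinite counts-to-zero
    plants included) at planted mean count >= ``min_mean_count`` in the
    genotype's control library.
    """
    de = bundle["de"]
    member = bundle["membership"].set_index("mirna_id")["membership"]
    novel_map = _novel_name_map(bundle["novel_calls"], truth)
    truth_by_name = {v: k for k, v in novel_map.items()}
    planted = truth.planted_de.set_index("mirna")
    total = correct = 0
    misses = []
    for tname, row in planted.iterrows():
        if row["membership"] == "none" or abs(row["lfc"]) < strong_lfc:
            continue
        geno = "HT" if row["membership"] in ("HT-only", "both") else "HS"
        control_mean = truth.planted_counts.at[tname, f"{geno}_0h"]
        base_mean = max(control_mean,
                        truth.planted_counts.loc[tname].max())
        if base_mean < min_mean_count:
            continue
        total += 1
        pid = tname if tname in member.index else truth_by_name.get(tname)
        if pid is None or pid not in member.index:
            misses.append((tname, "not-called"))
            continue
        sub = de[(de["mirna_id"] == pid)
                 & (de["contrast"].str.startswith(geno))]
        dir_ok = (sub["direction"] == row["direction"]).any()
        mem_ok = member[pid] == row["membership"]
        if dir_ok and mem_ok:
            correct += 1
        else:
            misses.append((tname, f"direction_ok={dir_ok} "
                                  f"membership={member.get(pid)}"))
    return {"n_strong": total, "n_recovered": correct,
            "recovery": correct / total if total else float("nan"),
            "misses": misses}


def novel_recovery(bundle: dict, truth: TruthTable,
                   min_reads: int = 10) -> dict:
    """Planted novel hairpins called pass, and the non-planted pass rate."""
    calls = bundle["novel_calls"]
    planted_seqs = {truth.mature_seqs[n] for n in truth.mature_seqs
                    if n.startswith("nov")}
    counts = bundle["counts"]
    # expression floor: planted precursor must actually be sequenced
    expressed = set()
    for name in truth.mature_seqs:
        if not name.startswith("nov"):
            continue
        if truth.planted_counts.loc[name].sum() >= min_reads:
            expressed.add(truth.mature_seqs[name])
    planted = calls[calls["sequence"].isin(expressed)]
    others = calls[~calls["sequence"].isin(planted_seqs)]
    n_pass = int((planted["verdict"] == "pass").sum())
    n_known_in_novel = sum(
        1 for m in counts.index
        if m.startswith("kno") and m in set(calls["novel_id"]))
    return {
        "n_planted": len(expressed),
        "n_recovered": n_pass,
        "recovery": n_pass / len(expressed) if expressed else float("nan"),
        "false_pass_rate": float((others["verdict"] == "pass").mean())
        if len(others) else 0.0,
        "known_leakage": n_known_in_novel,
    }


def ncrna_fraction_zscores(bundle: dict, truth: TruthTable,
                           config: SimConfig) -> pd.DataFrame:
    """Multinomial z-scores of recovered structural-RNA class fractions.

    The planted fraction applies to raw reads; recovered percentages are of
    clean reads, so the expectation is rescaled by the per-library clean
    fraction before the z-score.
    """
    cat = bundle["category_table"].set_index("category")
    stats = bundle["clean_stats"].set_index("library")
    rows = []
    for lib in stats.index:
        depth = config.library(lib).depth
        clean = stats.at[lib, "total_clean"]
        for cls, frac in config.ncrna_fractions.items():
            expected = frac * depth  # planted reads of the class
            observed = cat.at[cls, f"{lib}_count"]
            sd = np.sqrt(depth * frac * (1 - frac))
            rows.append(dict(library=lib, cls=cls, expected=expected,
                             observed=observed, clean=clean,
                             z=(observed - expected) / sd))
    return pd.DataFrame(rows)
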