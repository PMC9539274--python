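"""Group-level statistics on computed indices and pipeline orchestration.

Covers the intracluster correlation used to justify unit-level independence,
the nonparametric and contingency comparisons applied to grouping indices and
class proportions, the split-plot two-way ANOVA on burst-shape matrices, and
``run_pipeline`` which chains classification, burst detection, grouping,
shape and connectivity into one seeded, reproducible report bundle.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (AnalysisConfig, Recording, ValidationError,
                   as_seed_sequence, read_spike_table, write_spike_table)
from .bursts import (burst_rate, burst_shape, detect_population_bursts,
                     grouping_index, shape_bin_edges)
from .connect import connectivity_screen
from .patterns import ClassifierConfig, classify_pattern
from .synth import GeneratorParams, generate_condition_pair


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_between: float
    sigma2_within: float
    icc: float


@dataclass(frozen=True)
class ComparisonReport:
    test: str
    statistic: float
    p_value: float
    group_summaries: tuple    # ((mean, sem, n), ...) for sample inputs


# ---------------------------------------------------------------------------
# Intracluster correlation

def icc(values, group_ids) -> VarianceComponents:
    """One-way random-effects intracluster correlation (method of moments).

    Between-group and within-group variance components are estimated from the
    one-way ANOVA mean squares with the unbalanced-design group-size
    correction; a negative between estimate is truncated to zero. The ICC is
    the between component over the total, i.e. the similarity of observations
    within one group (here: neurons within one animal).
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "g": np.asarray(group_ids)})
    sizes = df.groupby("g").size().to_numpy()
    k, n = sizes.size, int(sizes.sum())
    if k < 2:
        raise ValidationError("icc needs at least two groups")
    if not np.any(sizes >= 2):
        raise ValidationError("icc needs at least one group with >= 2 values")
    grand = df["y"].mean()
    means = df.groupby("g")["y"].mean()
    ssb = float((sizes * (means.to_numpy() - grand) ** 2).sum())
    ssw = float(((df["y"] - df["g"].map(means)) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    n0 = (n - (sizes ** 2).sum() / n) / (k - 1)
    s2b = max(0.0, (msb - msw) / n0)
    total = s2b + msw
    return VarianceComponents(s2b, msw, s2b / total if total > 0 else 0.0)


# ---------------------------------------------------------------------------
# Two-group comparisons

def _summ(x):
    x = np.asarray(x, dtype=float)
    return (float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size)), int(x.size))


def compare_groups(sample_a, sample_b=None, test: str = "mann_whitney",
                   table=None) -> ComparisonReport:
    """Two-sided group comparison.

    ``mann_whitney`` and ``wilcoxon_paired`` take two samples;
    ``fisher_exact`` and ``chi_square`` take a 2x2 (or RxC for chi-square)
    contingency ``table``. Fisher's exact p is the two-sided sum of table
    probabilities no more likely than the observed one under fixed margins.
    """
    if test == "mann_whitney":
        stat, p = sps.mannwhitneyu(sample_a, sample_b, alternative="two-sided")
        return ComparisonReport(test, float(stat), float(p),
                                (_summ(sample_a), _summ(sample_b)))
    if test == "wilcoxon_paired":
        a, b = np.asarray(sample_a), np.asarray(sample_b)
        if a.size != b.size:
            raise ValidationError("paired test needs equal-length samples")
        stat, p = sps.wilcoxon(a, b)
        return ComparisonReport(test, float(stat), float(p),
                                (_summ(a), _summ(b)))
    if test in ("fisher_exact", "chi_square"):
        tab = np.asarray(table if table is not None else sample_a)
        if test == "fisher_exact":
            stat, p = sps.fisher_exact(tab, alternative="two-sided")
        else:
            stat, p, _, _ = sps.chi2_contingency(tab)
        sums = tuple((float(r.sum()), 0.0, int(r.sum())) for r in tab)
        return ComparisonReport(test, float(stat), float(p), sums)
    raise ValidationError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# Split-plot ANOVA on burst-shape matrices

def shape_anova(shape_rows_by_group: dict, alpha: float = 0.05) -> dict:
    """Two-way (group x time-bin) ANOVA on burst-shape matrices.

    ``shape_rows_by_group`` maps group name -> (units x bins) matrix. The
    design is split-plot: group is a between-unit factor tested against the
    unit-within-group mean square (df N - g); bin and the group x bin
    interaction are within-unit factors tested against the residual
    (df (N - g)(b - 1)). With two groups, per-bin two-sample t tests with a
    Sidak correction over the b bins form the post hoc family.
    """
    names = list(shape_rows_by_group)
    mats = [np.asarray(shape_rows_by_group[g], dtype=float) for g in names]
    if len(mats) < 2:
        raise ValidationError("shape_anova needs >= 2 groups")
    b = mats[0].shape[1]
    if any(m.shape[1] != b for m in mats):
        raise ValidationError("groups have mismatched bin counts")
    g = len(mats)
    sizes = np.array([m.shape[0] for m in mats])
    N = int(sizes.sum())
    Y = np.vstack(mats)                       # N x b
    grand = Y.mean()

    ss_total = float(((Y - grand) ** 2).sum())
    unit_means = Y.mean(axis=1)
    ss_subjects = float(b * ((unit_means - grand) ** 2).sum())
    group_means = np.array([m.mean() for m in mats])
    ss_group = float(b * (sizes * (group_means - grand) ** 2).sum())
    ss_subj_within = ss_subjects - ss_group

    bin_means = Y.mean(axis=0)
    # unweighted within-group bin profile keeps the partition orthogonal
    ss_bin = float(N * ((bin_means - grand) ** 2).sum())
    cell = np.stack([m.mean(axis=0) for m in mats])     # g x b
    ss_cells = float((sizes[:, None] * (cell - grand) ** 2).sum())
    ss_int = ss_cells - ss_group - ss_bin
    ss_resid = ss_total - ss_subjects - ss_bin - ss_int

    df_group, df_subj = g - 1, N - g
    df_bin = b - 1
    df_int = (g - 1) * (b - 1)
    df_resid = (N - g) * (b - 1)

    def f_p(ss, df, ms_err, df_err):
        ms = ss / df
        f = ms / ms_err if ms_err > 0 else 0.0
        return f, float(sps.f.sf(f, df, df_err))

    ms_subj = ss_subj_within / df_subj
    ms_resid = ss_resid / df_resid
    f_g, p_g = f_p(ss_group, df_group, ms_subj, df_subj)
    f_b, p_b = f_p(ss_bin, df_bin, ms_resid, df_resid)
    f_i, p_i = f_p(ss_int, df_int, ms_resid, df_resid)

    out = {
        "group": {"F": f_g, "df": (df_group, df_subj), "p": p_g},
        "bin": {"F": f_b, "df": (df_bin, df_resid), "p": p_b},
        "interaction": {"F": f_i, "df": (df_int, df_resid), "p": p_i},
        "n_units": {name: int(s) for name, s in zip(names, sizes)},
    }

    if g == 2:
        raw = np.array([sps.ttest_ind(mats[0][:, j], mats[1][:, j]).pvalue
                        for j in range(b)])
        raw = np.where(np.isnan(raw), 1.0, raw)
        adj = 1.0 - (1.0 - raw) ** b          # Sidak family = the b bins
        out["posthoc"] = {
            "p_adjusted": adj.tolist(),
            "significant_bins": np.flatnonzero(adj < alpha).tolist(),
        }
    return out


# ---------------------------------------------------------------------------
# Pipeline orchestration

def _analyse_recording(rec: Recording, config: AnalysisConfig,
                       cls_config: ClassifierConfig, seed) -> dict:
    """classify -> bursts -> grouping/shape for one recording."""
    bs = detect_population_bursts(rec, config)
    windows_exist = len(bs) > 0
    rows = []
    shapes = []
    gseed = as_seed_sequence(seed)
    for train, sub in zip(rec.neurons(), gseed.spawn(len(rec.neurons()))):
        label = classify_pattern(train, cls_config)
        gi = grouping_index(train, bs, rec.duration,
                            null_reps=config.null_reps, seed=sub)
        rows.append({
            "unit_id": train.unit_id,
            "condition": train.condition,
            "pattern": label.code if label else "unclassifiable",
            "n_spikes": train.n_spikes,
            "mean_rate_hz": train.rate(rec.duration),
            "grouping_pct": gi.grouping,
            "null_mean_pct": gi.null_mean,
            "null_sd_pct": gi.null_sd,
        })
        if windows_exist:
            shapes.append(burst_shape(train, bs, config))
    units = pd.DataFrame(rows)
    shape = np.vstack(shapes) if shapes else np.empty((0, config.n_shape_bins))
    return {"bursts": bs, "units": units, "shape": shape,
            "burst_rate_hz": burst_rate(bs, rec.duration)}


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the full analysis described by a config mapping.

    The config either names input files (``spikes``/``metadata`` CSV+JSON
    paths, optionally per condition) or requests a simulated naive/treated
    pair (``simulate: {...GeneratorParams fields...}``). Writes per-unit
    tables, shape matrices, the burst lists, an edge table when afferents are
    present, and a JSON summary; everything is derived from ``seed`` and the
    run is byte-reproducible.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    acfg = AnalysisConfig(**config.get("analysis", {}))
    ccfg = ClassifierConfig(**config.get("classifier", {}))

    recordings: dict[str, Recording] = {}
    if "simulate" in config:
        params = GeneratorParams(**{**config["simulate"], "seed": seed})
        rec_n, rec_t, _ = generate_condition_pair(params)
        recordings = {"naive": rec_n, "treated": rec_t}
        for name, rec in recordings.items():
            write_spike_table(rec, out / f"spikes_{name}.csv",
                              out / f"meta_{name}.json")
    elif "inputs" in config:
        for name, spec in config["inputs"].items():
            for key in ("spikes", "metadata"):
                if key not in spec or not Path(spec[key]).exists():
                    raise ValidationError(
                        f"input {name!r}: missing {key} file "
                        f"{spec.get(key, '<unset>')!r}")
            recordings[name] = read_spike_table(spec["spikes"], spec["metadata"])
    else:
        raise ValidationError("config needs either 'simulate' or 'inputs'")

    summary: dict = {"seed": seed, "groups": {}}
    results = {}
    for i, (name, rec) in enumerate(sorted(recordings.items())):
        try:
            res = _analyse_recording(rec, acfg, ccfg,
                                     np.random.SeedSequence(seed, spawn_key=(i,)))
        except ValidationError as exc:
            raise ValidationError(f"stage analyse[{name}]: {exc}") from exc
        results[name] = res
        res["units"].to_csv(out / f"units_{name}.csv", index=False)
        edges_mid = shape_bin_edges(acfg)[:-1] * 1000
        pd.DataFrame(res["shape"],
                     columns=[f"bin_{e:+.0f}ms" for e in edges_mid]) \
            .to_csv(out / f"shape_{name}.csv", index=False)
        pd.DataFrame({"mark_s": res["bursts"].marks,
                      "peak_freq_hz": res["bursts"].peak_freq}) \
            .to_csv(out / f"bursts_{name}.csv", index=False)
        g = res["units"]["grouping_pct"]
        summary["groups"][name] = {
            "n_units": int(len(res["units"])),
            "burst_rate_hz": round(res["burst_rate_hz"], 6),
            "grouping_mean_pct": round(float(g.mean()), 4),
            "grouping_sem_pct": round(float(g.std(ddof=1) / np.sqrt(len(g))), 4),
            "per_class_grouping_pct": {
                k: round(float(v), 4) for k, v in
                res["units"].groupby("pattern")["grouping_pct"].mean().items()
            },
        }
        if rec.afferents():
            edges = connectivity_screen(
                rec, config=acfg,
                seed=np.random.SeedSequence(seed, spawn_key=(1000 + i,)))
            edges.to_csv(out / f"edges_{name}.csv", index=False)
            summary["groups"][name]["n_edges"] = int(
                (edges["direction"] != "none").sum())

    if len(results) == 2:
        a, bname = sorted(results)
        ga = results[a]["units"]["grouping_pct"]
        gb = results[bname]["units"]["grouping_pct"]
        cmp_rep = compare_groups(ga, gb, "mann_whitney")
        anova = shape_anova({a: results[a]["shape"], bname: results[bname]["shape"]})
        summary["contrast"] = {
            "groups": [a, bname],
            "mann_whitney_p": cmp_rep.p_value,
            "anova_group_p": anova["group"]["p"],
            "anova_interaction_p": anova["interaction"]["p"],
        }

    summary_text = json.dumps(summary, indent=1, sort_keys=True)
    (out / "summary.json").write_text(summary_text)
    run_log = {"config_echo": {k: v for k, v in config.items()},
               "analysis_config": asdict(acfg),
               "classifier_config": asdict(ccfg)}
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1,
                                                 sort_keys=True, default=str))
    return summary
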