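"""End-to-end orchestration: simulate -> estimate -> select -> decode -> infer.

A study is a set of synthetic participants (independent ground-truth
draws sharing the design constants), each with two sessions.  Per
participant and session, raw runs are converted to %BOLD, per-run
sinusoidal response vectors estimated, and the four-stage voxel
selection fitted; decoding is strictly between sessions.  Group
summaries mirror the study's reporting: AUC per encoding and
condition-pair type, and condition-mean response vectors with delay and
amplitude effects plus bootstrap intervals.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .decode import cross_session_decode
from .design import StudyDesign
from .glm import circular_mean_vector, phase_to_delay, wrap_delay_difference
from .inference import (
    BootstrapCI,
    bootstrap_ci,
    one_sample_t,
    permutation_null_auc,
    rm_anova,
    signed_rank,
)
from .selection import SessionVoxelSelector, fit_session_selector
from .synth import GeneratorParams, build_ground_truth, simulate_study

__all__ = [
    "StudyConfig",
    "all_condition_pairs",
    "analyze_participant",
    "decode_participant",
    "condition_mean_vectors",
    "delay_amplitude_effects",
    "run_study",
    "summarize",
]


def all_condition_pairs(design: StudyDesign) -> list[tuple[str, str]]:
    c = design.conditions
    return [(c[0], c[1]), (c[0], c[2]), (c[1], c[2])]


@dataclass
class StudyConfig:
    """Everything that determines one study run (serializable round-trip)."""

    design: StudyDesign = field(default_factory=StudyDesign)
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    n_participants: int = 6
    n_voxels: int = 500
    encodings: tuple[str, ...] = ("delay", "amplitude", "both")
    n_permutations: int = 8192
    n_resamples: int = 8192
    svm_c: float = 1.0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "design": self.design.to_dict(),
            "generator": self.generator.to_dict(),
            "n_participants": self.n_participants,
            "n_voxels": self.n_voxels,
            "encodings": list(self.encodings),
            "n_permutations": self.n_permutations,
            "n_resamples": self.n_resamples,
            "svm_c": self.svm_c,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        d["design"] = StudyDesign.from_dict(d.get("design", {}))
        d["generator"] = GeneratorParams.from_dict(d.get("generator", {}))
        d["encodings"] = tuple(d.get("encodings", ("delay", "amplitude", "both")))
        return cls(**d)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "StudyConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))


# ----------------------------------------------------------------------
# per-participant analysis

def simulate_participant(
    config: StudyConfig, participant_seed: int
) -> list:
    """Ground truth + sessions for one participant."""
    ss = np.random.SeedSequence(entropy=(int(participant_seed), 0x9E3779B9))
    truth_seed, study_seed = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    truth, meta = build_ground_truth(
        config.design, config.n_voxels, config.generator, seed=truth_seed
    )
    return simulate_study(
        config.design, truth, seed=study_seed, params=config.generator, meta=meta
    )


def analyze_participant(sessions: Sequence) -> list[SessionVoxelSelector]:
    """Fit the per-session selection cascade (vectors estimated inside)."""
    return [fit_session_selector(ds) for ds in sessions]


def decode_participant(
    selectors: Sequence[SessionVoxelSelector],
    pairs: Sequence[tuple[str, str]],
    encodings: Sequence[str],
    C: float = 1.0,
) -> pd.DataFrame:
    """Between-session AUC for every condition pair and encoding."""
    rows = []
    vectors = [sel.run_vectors_ for sel in selectors]
    labels = [sel.labels_ for sel in selectors]
    masks = [sel.support_ for sel in selectors]
    for pair in pairs:
        for encoding in encodings:
            for res in cross_session_decode(vectors, labels, masks, pair, encoding, C=C):
                rows.append(
                    {
                        "pair": f"{pair[0]}|{pair[1]}",
                        "encoding": encoding,
                        "train_session": res.train_session,
                        "test_session": res.test_session,
                        "auc": res.auc,
                        "n_train": res.n_train,
                        "n_test": res.n_test,
                    }
                )
    return pd.DataFrame(rows)


def condition_mean_vectors(
    selectors: Sequence[SessionVoxelSelector], design: StudyDesign
) -> pd.DataFrame:
    """Voxel- and run-averaged response vector per condition.

    When averaging across voxels, each session uses the voxel selection
    derived from the *other* session (no circularity); runs of a
    condition are averaged as complex vectors, then sessions averaged.
    """
    n_ses = len(selectors)
    rows = []
    for condition in design.conditions:
        per_session = []
        for s, sel in enumerate(selectors):
            other = selectors[(s + 1) % n_ses]
            mask = other.support_
            runs = sel.run_vectors_[np.asarray(sel.labels_) == condition][:, mask]
            per_session.append(circular_mean_vector(runs))
        z = complex(np.mean(per_session))
        rows.append(
            {
                "condition": condition,
                "sin_coef": z.real,
                "cos_coef": z.imag,
                "amplitude": abs(z),
                "delay_seconds": float(phase_to_delay(z, design)),
            }
        )
    return pd.DataFrame(rows)


def delay_amplitude_effects(
    cond_vectors: pd.DataFrame, design: StudyDesign
) -> dict[str, float]:
    """Plaid-minus-gratings delay (circular, s) and amplitude (%BOLD) effects."""
    cv = cond_vectors.set_index("condition")
    gratings = [c for c in design.conditions if c != "plaid"]
    z_g = complex(
        np.mean([cv.loc[g, "sin_coef"] + 1j * cv.loc[g, "cos_coef"] for g in gratings])
    )
    z_p = complex(cv.loc["plaid", "sin_coef"] + 1j * cv.loc["plaid", "cos_coef"])
    d_g = float(phase_to_delay(z_g, design))
    d_p = float(phase_to_delay(z_p, design))
    return {
        "delay_diff_seconds": float(wrap_delay_difference(d_p - d_g, design)),
        "amplitude_diff_percent": abs(z_p) - abs(z_g),
        "grating_delay_seconds": d_g,
        "plaid_delay_seconds": d_p,
    }


# ----------------------------------------------------------------------
# study-level orchestration

def run_study(config: StudyConfig, out_dir: str | Path) -> Path:
    """Run the full synthetic study and write the result bundle.

    Writes ``config.yaml``, ``manifest.json``, per-run response-vector,
    mask and threshold tables, decode results, per-participant
    condition-mean vectors, permutation reports (when
    ``config.n_permutations > 0``) and the group summary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = config.to_yaml(out / "config.yaml")

    pairs = all_condition_pairs(config.design)
    child_seeds = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    vec_rows, mask_frames, decode_frames, cond_frames = [], [], [], []
    thresholds: dict[str, dict] = {}
    perm_reports = []
    for p_idx, child in enumerate(child_seeds):
        participant = f"sub-{p_idx + 1:02d}"
        p_seed = int(child.generate_state(1)[0] % (2**31))
        sessions = simulate_participant(config, p_seed)
        selectors = analyze_participant(sessions)
        for sel in selectors:
            frame = sel.to_frame()
            frame.insert(0, "session", sel.session_id_)
            frame.insert(0, "participant", participant)
            mask_frames.append(frame)
            thresholds[f"{participant}/ses-{sel.session_id_:02d}"] = {
                "vein_threshold": float(sel.vein_threshold_),
                "t2_threshold": float(sel.t2_threshold_),
                "n_selected": int(sel.support_.sum()),
            }
            vecs = sel.run_vectors_
            for r in range(vecs.shape[0]):
                z = vecs[r]
                vec_rows.append(
                    pd.DataFrame(
                        {
                            "participant": participant,
                            "session": sel.session_id_,
                            "run": r,
                            "condition": sel.labels_[r],
                            "voxel_id": np.arange(z.size),
                            "sin_coef": z.real,
                            "cos_coef": z.imag,
                            "amplitude": np.abs(z),
                        }
                    )
                )
        dec = decode_participant(selectors, pairs, config.encodings, C=config.svm_c)
        dec.insert(0, "participant", participant)
        decode_frames.append(dec)
        cond = condition_mean_vectors(selectors, config.design)
        cond.insert(0, "participant", participant)
        cond_frames.append(cond)

        if config.n_permutations > 0:
            perm_seed = int(child.generate_state(2)[1] % (2**31))
            labels = [sel.labels_ for sel in selectors]
            for k, (pair, encoding) in enumerate(
                [(p, e) for p in pairs for e in config.encodings]
            ):
                null = permutation_null_auc(
                    selectors,
                    labels,
                    pair,
                    encoding,
                    n_permutations=config.n_permutations,
                    seed=np.random.default_rng((perm_seed, k)),
                    C=config.svm_c,
                )
                perm_reports.append(
                    {
                        "participant": participant,
                        "pair": f"{pair[0]}|{pair[1]}",
                        "encoding": encoding,
                        "observed_auc": null.observed,
                        "p": null.p,
                        "significant": null.significant,
                        "n_permutations": null.n_permutations,
                    }
                )

    pd.concat(vec_rows, ignore_index=True).to_csv(out / "vectors.csv", index=False)
    pd.concat(mask_frames, ignore_index=True).to_csv(out / "masks.csv", index=False)
    (out / "thresholds.json").write_text(json.dumps(thresholds, indent=2, sort_keys=True))
    pd.concat(decode_frames, ignore_index=True).to_csv(out / "decode.csv", index=False)
    pd.concat(cond_frames, ignore_index=True).to_csv(
        out / "condition_vectors.csv", index=False
    )
    if perm_reports:
        (out / "permutation.json").write_text(json.dumps(perm_reports, indent=2))

    manifest = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": config.seed,
        "n_participants": config.n_participants,
        "stages": ["simulate", "estimate", "select", "decode", "infer", "summarize"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    summarize(out)
    return out


def summarize(bundle_dir: str | Path) -> dict:
    """Group summary tables from a result bundle (pure; regenerating from
    the same bundle gives identical output).

    Produces the AUC table per encoding and pair type, per-participant
    condition-mean vectors with the plaid-vs-grating delay and amplitude
    effects, bootstrap CIs over participants, and group tests when at
    least 3 participants are present.  Written to ``summary.json``,
    ``auc_summary.csv`` and ``effect_summary.csv``.
    """
    bundle = Path(bundle_dir)
    config = StudyConfig.from_yaml(bundle / "config.yaml")
    design = config.design
    decode = pd.read_csv(bundle / "decode.csv")
    cond = pd.read_csv(bundle / "condition_vectors.csv")
    participants = sorted(decode["participant"].unique())
    n = len(participants)
    gratings = [c for c in design.conditions if c != "plaid"]
    grating_pair = f"{gratings[0]}|{gratings[1]}"

    def pair_type(pair: str) -> str:
        return "grating|grating" if pair == grating_pair else "plaid|grating"

    decode = decode.assign(pair_type=decode["pair"].map(pair_type))
    per_part = (
        decode.groupby(["participant", "encoding"])["auc"].mean().unstack("encoding")
    )
    per_part_type = (
        decode.groupby(["participant", "encoding", "pair_type"])["auc"]
        .mean()
        .unstack(["encoding", "pair_type"])
    )

    auc_rows = []
    rng_seed = int(config.seed) + 101
    for encoding in config.encodings:
        values = per_part[encoding].to_numpy()
        row = {"encoding": encoding, "pair_type": "all", "auc": float(values.mean())}
        if n >= 2:
            ci = bootstrap_ci(
                lambda d: float(np.mean(d)),
                values,
                n_resamples=config.n_resamples,
                coverage=0.90,
                seed=rng_seed,
            )
            row.update(ci_low=float(ci.low), ci_high=float(ci.high))
        auc_rows.append(row)
        for ptype in ("grating|grating", "plaid|grating"):
            vals = per_part_type[(encoding, ptype)].to_numpy()
            auc_rows.append(
                {"encoding": encoding, "pair_type": ptype, "auc": float(vals.mean())}
            )
    auc_table = pd.DataFrame(auc_rows)

    effect_rows = []
    for participant, sub in cond.groupby("participant"):
        eff = delay_amplitude_effects(sub, design)
        eff["participant"] = participant
        effect_rows.append(eff)
    effects = pd.DataFrame(effect_rows)

    summary: dict = {
        "n_participants": n,
        "auc_table": auc_table.to_dict(orient="records"),
        "effects": effects.to_dict(orient="records"),
    }
    if n >= 2:
        diffs = effects["delay_diff_seconds"].to_numpy()
        ci = bootstrap_ci(
            lambda d: float(np.mean(d)),
            diffs,
            n_resamples=config.n_resamples,
            coverage=0.95,
            seed=rng_seed + 1,
        )
        summary["group_delay_effect"] = {
            "mean_seconds": float(diffs.mean()),
            "ci_low": float(ci.low),
            "ci_high": float(ci.high),
            "ci_width": float(ci.width),
        }
    if n >= 3:
        diffs = effects["delay_diff_seconds"].to_numpy()
        delays = []
        for participant in participants:
            sub = cond[cond["participant"] == participant].set_index("condition")
            z = {
                c: complex(sub.loc[c, "sin_coef"] + 1j * sub.loc[c, "cos_coef"])
                for c in design.conditions
            }
            ref = float(phase_to_delay(np.mean(list(z.values())), design))
            delays.append(
                [
                    ref
                    + float(
                        wrap_delay_difference(
                            float(phase_to_delay(z[c], design)) - ref, design
                        )
                    )
                    for c in design.conditions
                ]
            )
        summary["group_tests"] = {
            "delay_t": one_sample_t(diffs, 0.0, alternative="two-sided").to_dict(),
            "delay_signed_rank": signed_rank(diffs).to_dict(),
            "delay_rm_anova": rm_anova(np.asarray(delays)).to_dict(),
        }

    auc_table.to_csv(bundle / "auc_summary.csv", index=False)
    effects.to_csv(bundle / "effect_summary.csv", index=False)
    (bundle / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
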