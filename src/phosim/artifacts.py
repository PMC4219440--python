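"""Session orchestration and run artifacts.

:func:`run_session` wires the pieces together: sentences, schedule,
patterns, synthetic gaze, the trial engine, and scoring.
:func:`write_run_artifacts` persists everything (trial log, score
tables, patterns, config copy) together with a manifest of SHA-256
content hashes, so a run can be verified and reproduced bit-for-bit
from its seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from . import trial_engine as te
from .config import RunConfig, save_config
from .patterns import TIERS, default_profile, generate_pattern
from .scoring import ScoreTable, score_log
from .stimuli import generate_sentence


@dataclass
class SessionResult:
    sentences: dict
    schedule: list
    patterns: dict
    records: list
    log: "object"
    scores: ScoreTable


def run_session(
    config: RunConfig | None = None, frame_sink=None, render: bool = True
) -> SessionResult:
    """Run one complete synthetic 48-trial session.

    Sentences, patterns, and gaze are all derived from the named seeds
    in the config.  ``render=False`` skips gaze-contingent frame
    generation (the reading outcomes do not depend on it; the scripted
    observer supplies word errors either way).
    """
    cfg = config or RunConfig()
    n_trials = len(cfg.stimuli.font_ladder) * len(te.VIEWING_CONDITIONS) * 2
    sentences = {}
    for i in range(n_trials):
        sid = f"s{i + 1:02d}"
        sentences[sid] = generate_sentence(
            seed=(cfg.seeds.sentences * 1_000_003 + i) % 2**31
        )
    schedule = te.build_schedule(list(sentences))
    profile = default_profile(cfg.rho_max_deg)
    patterns = {
        tier: generate_pattern(tier, profile, seed=(cfg.seeds.pattern * 31 + k) % 2**31)
        for k, tier in enumerate(TIERS)
    }
    reader = te.SyntheticReader(
        midpoints=cfg.reader.midpoints(),
        slope_per_logmar=cfg.reader.slope_per_logmar,
        seed=cfg.seeds.gaze,
    )
    records = te.run_block(
        schedule,
        sentences,
        patterns if render else {},
        display=cfg.display,
        engine=cfg.engine,
        gaze_params=cfg.gaze,
        reader=reader,
        gaze_seed=cfg.seeds.gaze,
        stimulus_cache={},
        frame_sink=frame_sink,
        rasterize_kwargs={
            "font_path": cfg.stimuli.font_file,
            "tracking": cfg.stimuli.tracking,
            "line_spacing_em": cfg.stimuli.line_spacing_em,
        },
    )
    log = te.records_to_log(records, gaze_seed=cfg.seeds.gaze)
    scores = score_log(log, sizes=cfg.stimuli.font_ladder)
    return SessionResult(sentences, schedule, patterns, records, log, scores)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_run_artifacts(result: SessionResult, config: RunConfig, out_dir) -> dict:
    """Write trial log, scores, patterns, config, and a hash manifest.

    Returns the manifest mapping each written file name to its SHA-256.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    log_path = out / "trial_log.csv"
    result.log.to_csv(log_path, index=False)
    files.append(log_path)

    by_class = out / "scores_by_class.csv"
    result.scores.by_class.to_csv(by_class, index=False)
    files.append(by_class)
    by_cond = out / "scores_by_condition.csv"
    result.scores.by_condition.to_csv(by_cond, index=False)
    files.append(by_cond)
    scores_json = out / "scores.json"
    scores_json.write_text(result.scores.to_json())
    files.append(scores_json)

    for tier, pattern in result.patterns.items():
        p = out / f"pattern_{tier}.json"
        p.write_text(pattern.to_json())
        files.append(p)

    cfg_path = out / "config.yaml"
    save_config(config, cfg_path)
    files.append(cfg_path)

    sentences_path = out / "sentences.txt"
    sentences_path.write_text(
        "".join(s.text + "\n" for s in result.sentences.values())
    )
    files.append(sentences_path)

    manifest = {f.name: _sha256(f) for f in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def verify_manifest(out_dir) -> list[str]:
    """Re-hash the files listed in a run's manifest; returns the names
    whose content no longer matches (empty list = intact)."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    bad = []
    for name, digest in manifest.items():
        p = out / name
        if not p.exists() or _sha256(p) != digest:
            bad.append(name)
    return bad
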