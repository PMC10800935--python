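import numpy as np
import pytest

from sdsephys import synth


@pytest.fixture(scope="session")
def short_session():
    """A 2-min EEG-style session with one combined LFP+EMG artifact."""
    cfg = synth.LfpSimConfig(
        duration_s=120.0,
        fs_hz=400.0,
        channel_role="EEG",
        drug_time_s=60.0,
        artifact_epochs=(synth.ArtifactEpoch(10.2, 2.5, 5.0, 5.0),),
        seed=101,
    )
    return synth.simulate_lfp_session(cfg)


@pytest.fixture(scope="session")
def default_patch():
    """A default patch trace: tonic -10 pA baseline, -15 pA drug shift."""
    return synth.simulate_patch_trace(synth.PatchSimConfig(seed=202))


def match_events(detected_onsets, true_onsets, tol_s=0.005):
    """Greedy one-to-one matching of detected to true onsets within tol."""
    detected_onsets = np.asarray(detected_onsets)
    used, tp = set(), 0
    for t_true in true_onsets:
        cand = [
            i
            for i, t in enumerate(detected_onsets)
            if abs(t - t_true) <= tol_s and i not in used
        ]
        if cand:
            used.add(min(cand, key=lambda i: abs(detected_onsets[i] - t_true)))
            tp += 1
    return tp
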