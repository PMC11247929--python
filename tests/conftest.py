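import numpy as np
import pytest

from v1calcium import preprocess as pp
from v1calcium import synthetic as syn
from v1calcium import tuning as tn


@pytest.fixture(scope="session")
def orientation_session():
    """100-neuron orientation session at default generator conditions.

    Neurons 0-59 are visually driven (random preferred orientations);
    60-99 have no visual gain.  Returns (recording, schedule, activity,
    neurons).
    """
    sched = syn.StimulusSchedule.orientation(n_repeats=10, seed=11)
    speed = syn.gen_locomotion(sched.duration_s, seed=12)
    rng = np.random.default_rng(13)
    neurons = [
        syn.GroundTruthNeuron(
            id=i,
            visual_gain=5.0 if i < 60 else 0.0,
            pref_orientation=float(rng.uniform(0, 360)),
            tuning_concentration=float(rng.uniform(1.0, 4.0)),
        )
        for i in range(100)
    ]
    rec = syn.gen_recording(neurons, sched, speed, seed=14)
    act = pp.preprocess_traces(rec.f_soma, rec.f_neuropil, rec.frame_rate)
    return rec, sched, act, neurons


@pytest.fixture(scope="session")
def orientation_table(orientation_session):
    _, sched, act, _ = orientation_session
    return tn.extract_trial_responses(act, sched)


@pytest.fixture(scope="session")
def coupling_results():
    """Speed-coupling recovery over three 730 s spontaneous sessions.

    Each session has 20 speed-coupled and 20 uncoupled neurons; activity
    and speed go through the full 5 Hz chain and the zero-lag shuffle
    test with the circular-shift null (the sample-permutation null is
    liberal on traces the smoothing chain has autocorrelated).  Returns
    (r, significant, coupled_mask) pooled over sessions.
    """
    from v1calcium import state as st

    rs, sigs, coupled = [], [], []
    sched = syn.StimulusSchedule.spontaneous(730.0)
    for k in range(3):
        speed = syn.gen_locomotion(730.0, seed=21 + 2 * k)
        neurons = [
            syn.GroundTruthNeuron(
                id=i,
                speed_coupling=0.5 if i < 20 else 0.0,
                run_gain=2.0 if i < 20 else 1.0,
            )
            for i in range(40)
        ]
        rec = syn.gen_recording(neurons, sched, speed, seed=22 + 2 * k)
        act = pp.preprocess_traces(rec.f_soma, rec.f_neuropil, rec.frame_rate)
        act5 = pp.resample_5hz(act.values, rec.frame_rate)
        speed5 = pp.resample_5hz(speed, rec.frame_rate)
        for i in range(40):
            res = st.xcorr_speed(act5[i], speed5, n_shuffles=1000,
                                 seed=500 + 40 * k + i, null="circular")
            rs.append(res.r_zero)
            sigs.append(res.significant)
            coupled.append(i < 20)
    return np.array(rs), np.array(sigs), np.array(coupled)
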