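import numpy as np
import pytest

from hragree.preprocess import PatientSession
from hragree.streams import HRStream


def make_session(ecg_hr, ppg_hr=None, qi=None, patient_id="P001",
                 phase="surgery", lag=0, arrhythmia=None):
    """Aligned session on a shared 0-based grid (test helper)."""
    ecg_hr = np.asarray(ecg_hr, dtype=float)
    ppg_hr = ecg_hr.copy() if ppg_hr is None else np.asarray(ppg_hr, dtype=float)
    n = ecg_hr.size
    t = np.arange(n, dtype=np.int64)
    qi = np.full(n, 4, dtype=np.int64) if qi is None else np.asarray(qi)
    ecg = HRStream(t=t, hr=ecg_hr, qi=np.full(n, 4, dtype=np.int64),
                   source="ECG", phase=phase)
    ppg = HRStream(t=t, hr=ppg_hr, qi=qi, source="PPG", phase=phase,
                   arrhythmia=arrhythmia)
    return PatientSession(patient_id=patient_id, phase=phase, ecg=ecg,
                          ppg=ppg, lag_applied=lag)


@pytest.fixture
def rng():
    return np.random.default_rng(20210427)
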