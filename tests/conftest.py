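import numpy as np
import pytest

from rulakit.landmarks import Landmark, LandmarkFrame, N_LANDMARKS, SessionStream
from rulakit.simulate import LiftingProfile

# short phase structure for tests that only need the phase shape, not 60 s
SHORT_PHASES = {"initiation": 1.0, "peak": 2.0, "sustained": 1.0, "recovery": 1.0}


@pytest.fixture
def short_profile():
    return LiftingProfile(phase_durations=dict(SHORT_PHASES), noise_sd=0.0, seed=0)


def make_frame(positions: np.ndarray, visibilities=None, t: float = 0.0) -> LandmarkFrame:
    """Build a frame from a (33, 3) position array."""
    if visibilities is None:
        visibilities = np.ones(N_LANDMARKS)
    lms = tuple(
        Landmark(float(p[0]), float(p[1]), float(p[2]), float(v))
        for p, v in zip(positions, visibilities)
    )
    return LandmarkFrame(timestamp=t, landmarks=lms)


def random_stream(rng: np.random.Generator, n_frames: int = 100, fps: float = 30.0) -> SessionStream:
    """A structurally valid stream of random (but finite) landmark data."""
    ts = np.arange(n_frames) / fps
    pos = rng.normal(0.0, 1.0, (n_frames, N_LANDMARKS, 3))
    vis = rng.uniform(0.0, 1.0, (n_frames, N_LANDMARKS))
    frames = [make_frame(pos[i], vis[i], t=float(ts[i])) for i in range(n_frames)]
    return SessionStream(frames=frames, nominal_fps=fps, metadata={"participant": "TEST"})


# MediaPipe left/right landmark index pairs, for sagittal-mirror tests
MIRROR_PAIRS = [
    (1, 4), (2, 5), (3, 6), (7, 8), (9, 10), (11, 12), (13, 14), (15, 16),
    (17, 18), (19, 20), (21, 22), (23, 24), (25, 26), (27, 28), (29, 30), (31, 32),
]


def mirror_frame(frame: LandmarkFrame) -> LandmarkFrame:
    """Reflect a frame through the sagittal plane: negate x, swap sides."""
    lms = list(frame.landmarks)
    for a, b in MIRROR_PAIRS:
        lms[a], lms[b] = lms[b], lms[a]
    lms = [Landmark(-p.x, p.y, p.z, p.visibility) for p in lms]
    return LandmarkFrame(timestamp=frame.timestamp, landmarks=tuple(lms))
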