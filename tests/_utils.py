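import numpy as np


def normalized(p: np.ndarray) -> np.ndarray:
    return p / np.max(np.abs(p))


def resample_common(sig_a, sig_b):
    """Interpolate two signals onto their overlapping uniform ct range."""
    lo = max(sig_a.ct[0], sig_b.ct[0])
    hi = min(sig_a.ct[-1], sig_b.ct[-1])
    step = min(sig_a.bin_width, sig_b.bin_width)
    ct = np.arange(lo, hi, step)
    return (
        ct,
        np.interp(ct, sig_a.ct, sig_a.p),
        np.interp(ct, sig_b.ct, sig_b.p),
    )
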