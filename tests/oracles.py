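"""Independent reference implementations used by several test modules."""

import numpy as np


def oracle_eer(genuine, impostor):
    """Exhaustive-sweep EER oracle.

    Enumerates every operating point by sweeping all distinct score
    thresholds, keeps the upper convex hull by an O(n^3) point-below-segment
    test, and intersects the hull with the FAR = FRR diagonal.  Shares no
    code with the implementation under test.
    """
    genuine = np.asarray(genuine, float)
    impostor = np.asarray(impostor, float)
    thr = np.unique(np.concatenate([genuine, impostor, [np.inf]]))
    pts = sorted({(float(np.mean(impostor >= t)), float(np.mean(genuine >= t)))
                  for t in thr} | {(0.0, 0.0), (1.0, 1.0)})

    def below(p, a, b):
        if not (a[0] <= p[0] <= b[0]) or a[0] == b[0]:
            return False
        w = (p[0] - a[0]) / (b[0] - a[0])
        return p[1] < a[1] + w * (b[1] - a[1]) - 1e-12

    hull = sorted(p for p in pts
                  if not any(below(p, a, b) for a in pts for b in pts if a < b))
    for (x1, y1), (x2, y2) in zip(hull, hull[1:]):
        f1, f2 = y1 + x1 - 1, y2 + x2 - 1
        if f1 <= 0 <= f2:
            if f2 == f1:
                return x2
            w = -f1 / (f2 - f1)
            return x1 + w * (x2 - x1)
    raise AssertionError("no diagonal crossing")
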