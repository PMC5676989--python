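"""End-to-end glue: continuous stream -> ensemble features dataset.

Each contact run of a stream is framed (5 s window, 1 s step), each frame
denoised and reduced to one ensemble heartbeat; frames that yield no usable
beat (flat signal, all templates saturated) are skipped.  A cohort of
annotated streams becomes a :class:`wheelbeat.evaluate.FrameDataset` ready
for protocol evaluation.
"""

from __future__ import annotations

import numpy as np

from wheelbeat.denoise import DenoiseConfig, denoise_frame
from wheelbeat.evaluate import FrameDataset
from wheelbeat.features import dct_features, haar_features
from wheelbeat.prepare import EnsembleHeartbeat, RpeakConfig, prepare_frame
from wheelbeat.stream_prep import EcgStream, frame_stream

__all__ = ["extract_ensembles", "cohort_dataset"]


def extract_ensembles(stream: EcgStream, denoise_cfg: DenoiseConfig | None = None,
                      rpeak_cfg: RpeakConfig | None = None, n: int = 3,
                      eps0: float = 0.1,
                      ) -> list[tuple[float, EnsembleHeartbeat]]:
    """(frame start time, ensemble heartbeat) for every productive frame."""
    out = []
    for frame in frame_stream(stream):
        cleaned = denoise_frame(frame, denoise_cfg)
        ens, _ = prepare_frame(cleaned, frame.fs, n=n, eps0=eps0,
                               rpeak_cfg=rpeak_cfg)
        if ens is not None:
            out.append((frame.start_s, ens))
    return out


def cohort_dataset(streams, scheme: str = "DCT",
                   denoise_cfg: DenoiseConfig | None = None,
                   rpeak_cfg: RpeakConfig | None = None, n: int = 3,
                   eps0: float = 0.1) -> FrameDataset:
    """Run the full preparation + feature chain over a cohort of streams.

    ``streams`` are :class:`wheelbeat.synthetic.AnnotatedStream` (or any
    object with ``to_stream()``, ``subject`` and ``meta['trip']``).
    """
    X, y, t, group = [], [], [], []
    for k, st in enumerate(streams):
        es = st.to_stream() if hasattr(st, "to_stream") else st
        label = getattr(st, "subject", f"S{k:02d}")
        trip = getattr(st, "meta", {}).get("trip", k)
        for start_s, ens in extract_ensembles(es, denoise_cfg, rpeak_cfg,
                                              n=n, eps0=eps0):
            if scheme == "DCT":
                fv = dct_features(ens, es.fs)
            elif scheme == "HAAR2":
                fv = haar_features(ens, es.fs)
            else:
                raise ValueError(f"unknown feature scheme {scheme!r}")
            X.append(fv.values)
            y.append(label)
            t.append(start_s)
            group.append(f"{label}/trip{trip}")
    if not X:
        raise ValueError("no frame of any stream produced an ensemble")
    return FrameDataset(X=np.stack(X), y=np.asarray(y), t=np.asarray(t),
                        group=np.asarray(group))
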