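"""Audio and configuration I/O, result writers and run manifests."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .config import AppraisalConfig, default_config
from .errors import AudioIOError, InvalidConfigError

__all__ = ["read_audio", "write_audio", "load_config", "save_config",
           "config_hash", "RunManifest"]

log = logging.getLogger(__name__)

_PCM_SCALE = {np.dtype("int16"): 2 ** 15, np.dtype("int32"): 2 ** 31}


def read_audio(path):
    """Read a WAV file as float samples in [-1, 1] plus the sample rate.

    PCM 16/24/32-bit and IEEE float files are supported; multichannel audio
    is averaged to mono (logged).  Unreadable or truncated files raise
    :class:`AudioIOError` without a partial result.
    """
    from scipy.io import wavfile

    try:
        sample_rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises bare ValueError on bad files
        raise AudioIOError(f"cannot read WAV file {path!r}: {exc}") from exc
    data = np.asarray(data)
    if data.dtype in _PCM_SCALE:
        samples = data.astype(float) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.uint8:
        samples = (data.astype(float) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(float)
    else:
        raise AudioIOError(f"unsupported WAV sample format {data.dtype}")
    if samples.ndim == 2:
        log.info("averaging %d channels of %s to mono", samples.shape[1], path)
        samples = samples.mean(axis=1)
    return samples, int(sample_rate)


def write_audio(path, samples, sample_rate: int) -> None:
    """Write float samples as a 32-bit float WAV file."""
    from scipy.io import wavfile

    try:
        wavfile.write(path, int(sample_rate),
                      np.asarray(samples, dtype=np.float32))
    except Exception as exc:
        raise AudioIOError(f"cannot write WAV file {path!r}: {exc}") from exc


def load_config(path=None) -> AppraisalConfig:
    """Load an appraisal configuration, or the embedded defaults.

    A user file (YAML or JSON) overrides the defaults field-wise: rows, if
    present, replace the default row set; scalar fields are merged.
    """
    if path is None:
        return default_config()
    try:
        with open(path) as fh:
            text = fh.read()
    except OSError as exc:
        raise AudioIOError(f"cannot read config {path!r}: {exc}") from exc
    if str(path).endswith((".yml", ".yaml")):
        import yaml

        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    if not isinstance(payload, dict):
        raise InvalidConfigError("config file must hold a mapping")
    return AppraisalConfig.from_dict(payload)


def save_config(config: AppraisalConfig, path) -> None:
    payload = config.to_dict()
    if str(path).endswith((".yml", ".yaml")):
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)
    else:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def config_hash(config: AppraisalConfig) -> str:
    """Stable hash of the full configuration (canonical JSON, SHA-256)."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every CLI result."""

    inputs: list
    config_hash: str
    seed: int | None = None
    stage: str = ""
    version: str = "0.1.0"
    timestamp: float = field(default_factory=time.time)
    extra: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)
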