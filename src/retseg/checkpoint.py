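"""Checkpointing: a network's configuration plus its exact parameter state.

Parameters and batch-norm running statistics are stored unmodified in an
``.npz`` archive together with the YAML-serialised network configuration, so
a round trip restores bit-identical forward behaviour.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .network import MultiDecoderUNet, NetworkConfig, build_network

__all__ = ["save_checkpoint", "load_checkpoint"]

_CONFIG_KEY = "__network_config_yaml__"


def save_checkpoint(net: MultiDecoderUNet, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = net.state_dict()
    config_yaml = yaml.safe_dump(net.config.to_dict())
    np.savez(path, **state, **{_CONFIG_KEY: np.frombuffer(config_yaml.encode(), np.uint8)})


def load_checkpoint(path) -> MultiDecoderUNet:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path) as archive:
        config_yaml = bytes(archive[_CONFIG_KEY]).decode()
        state = {k: archive[k] for k in archive.files if k != _CONFIG_KEY}
    config = NetworkConfig.from_dict(yaml.safe_load(config_yaml))
    net = build_network(config, seed=0)
    net.load_state_dict(state)
    return net
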