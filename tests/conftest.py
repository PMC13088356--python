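import numpy as np
import pytest

from filamap.io_preprocess import ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiff_factory(tmp_path):
    """Write an (C,Y,X) or (C,Z,Y,X) array as a calibrated TIFF, return path."""
    import tifffile

    def _write(pixels, name="img.tif", **imwrite_kwargs):
        path = tmp_path / name
        tifffile.imwrite(path, np.asarray(pixels, dtype=np.float32), **imwrite_kwargs)
        return path

    return _write


def make_stack(pixels, pixel_size=0.032, channel_names=None):
    pixels = np.asarray(pixels, dtype=float)
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(pixels.shape[0])]
    return ImageStack(pixels, pixel_size, channel_names)
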