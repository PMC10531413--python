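import numpy as np
import pytest

from fuzzyvit.phantom import PhantomParams, phantom_for_index

BANK_SEED = 1
BANK_N_PER_CLASS = 100


@pytest.fixture(scope="session")
def phantom_bank():
    """200 labeled phantoms (100 benign, 100 malignant) at the desk size.

    Images are raw generator output in [0, 1]; labels are 0=benign,
    1=malignant. Generated once per session with the same counter scheme
    ``write_dataset`` uses.
    """
    params = PhantomParams(seed=BANK_SEED)
    images, labels = [], []
    for class_idx, lab in enumerate(("benign", "malignant")):
        for i in range(BANK_N_PER_CLASS):
            item = phantom_for_index(params, class_idx * BANK_N_PER_CLASS + i, lab)
            images.append(item.image)
            labels.append(class_idx)
    return np.stack(images), np.asarray(labels)
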