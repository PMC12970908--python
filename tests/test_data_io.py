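"""Tests of splitting, partitioning, augmentation, preprocessing and the
synthetic leaf generator."""

import numpy as np
import pytest

from leafrgn.data_io import (ClassSpec, DatasetSplit, SampleRecord, SplitSpec,
                             augment_mirror_rotate, default_class_specs,
                             label_partition, preprocess, read_class_folders,
                             round_half_up, split_dataset, synth_generate,
                             write_class_folders)


def _records(n, label="x"):
    return [SampleRecord(image=i, label=label) for i in range(n)]


class TestSplitDataset:
    def test_full_corpus_three_way_arithmetic(self):
        """54,303 records at 6:2:2 give 32,581 / 10,861 / 10,861."""
        split = split_dataset(_records(54_303), SplitSpec(per_class=False))
        assert (len(split.train), len(split.validation), len(split.test)) == \
            (32_581, 10_861, 10_861)

    def test_small_three_way(self):
        split = split_dataset(_records(10), SplitSpec(per_class=False))
        assert (len(split.train), len(split.validation), len(split.test)) == (6, 2, 2)

    @pytest.mark.parametrize("n,expected", [(558, (391, 167)), (463, (324, 139))])
    def test_two_way_detection_split(self, n, expected):
        split = split_dataset(_records(n), SplitSpec(ratios=(0.7, 0.3),
                                                     per_class=False))
        assert (len(split.train), len(split.test)) == expected
        assert split.validation == []

    def test_partition_properties(self):
        records = [SampleRecord(image=i, label=f"c{i % 3}") for i in range(101)]
        spec = SplitSpec(seed=5)
        split = split_dataset(records, spec)
        ids = lambda part: {r.image for r in part}
        all_ids = ids(split.train) | ids(split.validation) | ids(split.test)
        assert all_ids == set(range(101))
        assert not ids(split.train) & ids(split.validation)
        assert not ids(split.train) & ids(split.test)
        assert not ids(split.validation) & ids(split.test)
        # stable under the same seed
        again = split_dataset(records, spec)
        assert ids(again.test) == ids(split.test)

    def test_labeled_fraction_marks_training_pool(self):
        split = split_dataset(_records(100), SplitSpec(
            per_class=False, labeled_fraction=0.3))
        assert len(split.train_labeled) == round_half_up(0.3 * len(split.train))
        assert all(not r.labeled and r.label is None for r in split.train_unlabeled)
        assert split.labeled_fraction == 0.3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split_dataset([], SplitSpec())


class TestLabelPartition:
    # every labeled/unlabeled cell of the five-group division of 32,581
    @pytest.mark.parametrize("fraction,expected", [
        (0.1, (3_258, 29_323)),
        (0.3, (9_774, 22_807)),
        (0.5, (16_291, 16_290)),   # fixes round-half-up
        (0.7, (22_807, 9_774)),
        (0.9, (29_323, 3_258)),
    ])
    def test_five_group_cells(self, fraction, expected):
        labeled, unlabeled = label_partition(_records(32_581), fraction, seed=0)
        assert (len(labeled), len(unlabeled)) == expected

    def test_full_fraction_and_determinism(self):
        pool = _records(17)
        labeled, unlabeled = label_partition(pool, 1.0, seed=3)
        assert len(labeled) == 17 and unlabeled == []
        a, _ = label_partition(pool, 0.4, seed=3)
        b, _ = label_partition(pool, 0.4, seed=3)
        assert [r.image for r in a] == [r.image for r in b]

    def test_invalid_fraction(self):
        with pytest.raises(ValueError, match="fraction"):
            label_partition(_records(5), 0.0, seed=0)


class TestAugmentation:
    def test_triples_the_pool(self, rng):
        images = [rng.uniform(size=(4, 4, 3)) for _ in range(186)]
        assert len(augment_mirror_rotate(images)) == 558

    def test_empty_input(self):
        assert augment_mirror_rotate([]) == []

    def test_mirror_involution_and_order(self, rng):
        img = rng.uniform(size=(6, 6, 3)).astype("f4")
        out = augment_mirror_rotate([img])
        assert len(out) == 3
        np.testing.assert_array_equal(out[0], img)
        np.testing.assert_array_equal(out[1][:, ::-1], img)     # mirror of mirror
        np.testing.assert_array_equal(out[2][::-1, ::-1], img)  # rot180 twice
        assert all(o.shape == img.shape for o in out)


class TestPreprocess:
    def test_resizes_large_image(self, rng):
        big = (rng.uniform(size=(1944, 2592, 3)) * 255).astype("u1")
        out = preprocess(big)
        assert out.shape == (128, 128, 3)
        assert out.dtype == np.float32
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_conforming_input_round_trips(self, rng):
        img = (rng.integers(0, 256, size=(128, 128, 3))).astype("u1")
        out = preprocess(img)
        np.testing.assert_allclose(out, img / 255.0, atol=1e-7)

    def test_unreadable_file_mentions_path(self, tmp_path):
        bad = tmp_path / "not_an_image.png"
        bad.write_text("plain text")
        with pytest.raises(OSError, match="not_an_image"):
            preprocess(bad)


class TestSynthGenerator:
    def test_empty_and_deterministic(self):
        images, labels, names, _ = synth_generate(0, seed=1, side=32)
        assert len(images) == 0 and len(labels) == 0 and len(names) == 4
        a = synth_generate(3, seed=42, side=32, n_unlabeled=2)
        b = synth_generate(3, seed=42, side=32, n_unlabeled=2)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[3], b[3])

    def test_healthy_vs_diseased_pixel_statistic_separable(self):
        """A lesion-pixel-fraction threshold separates healthy from diseased.

        Lesion colours are far from leaf green, so counting pixels closer
        to any lesion colour than to green should classify nearly all
        synthetic images, confirming the fixture is learnable.
        """
        specs = default_class_specs()
        images, labels, names, _ = synth_generate(50, specs, seed=11)
        healthy_idx = names.index("healthy")
        lesion_colors = np.array([s.lesion_color for s in specs
                                  if s.lesion_count[1] > 0])
        frac = []
        for img in images:
            d_lesion = np.min([((img - c) ** 2).sum(-1) for c in lesion_colors], axis=0)
            frac.append((d_lesion < 0.008).mean())
        frac = np.asarray(frac)
        is_diseased = labels != healthy_idx
        acc = ((frac > 0.005) == is_diseased).mean()
        assert acc > 0.90

    def test_per_class_lesion_statistics_distinct(self):
        """Mean lesion-pixel fraction ranks the disease classes as specified."""
        specs = default_class_specs()
        images, labels, names, _ = synth_generate(20, specs, seed=5)
        fracs = {}
        for ci, spec in enumerate(specs):
            if spec.lesion_count[1] == 0:
                continue
            color = np.array(spec.lesion_color)
            d = ((images[labels == ci] - color) ** 2).sum(-1)
            fracs[spec.name] = (d < 0.008).mean()
        assert all(f > 0.005 for f in fracs.values())

    def test_label_block_structure_and_range(self, tiny_synth):
        images, labels, names, unlabeled = tiny_synth
        assert images.shape == (48, 32, 32, 3)
        assert unlabeled.shape == (8, 32, 32, 3)
        assert images.min() >= 0.0 and images.max() <= 1.0
        np.testing.assert_array_equal(np.unique(labels), np.arange(4))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="two class"):
            synth_generate(2, [ClassSpec("only")], seed=0)
        with pytest.raises(ValueError, match="count"):
            ClassSpec("bad", lesion_count=(5, 2))


def test_folder_round_trip(tmp_path, tiny_synth):
    images, labels, names, unlabeled = tiny_synth
    write_class_folders(tmp_path, images[:8], labels[:8], names, unlabeled[:2])
    records = read_class_folders(tmp_path)
    assert sum(r.labeled for r in records) == 8
    assert sum(not r.labeled for r in records) == 2
    arr = preprocess(records[0].image, side=32)
    assert arr.shape == (32, 32, 3)
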