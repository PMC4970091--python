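"""Patch extraction, keypoints, descriptors, vocabulary and classification."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from phenonode.bovw import (
    DESCRIPTOR_DIM,
    NODE,
    NON_NODE,
    build_vocabulary,
    classify_candidate,
    describe,
    detect_keypoints,
    encode,
    extract_patch,
    train_patch_classifier,
)
from phenonode.skeleton import Candidate


def harris_response_oracle(gray, k=0.04, sigma=1.0):
    """Structure-tensor Harris response, computed independently."""
    gy, gx = np.gradient(gray)
    axx = gaussian_filter(gx * gx, sigma)
    ayy = gaussian_filter(gy * gy, sigma)
    axy = gaussian_filter(gx * gy, sigma)
    return axx * ayy - axy**2 - k * (axx + ayy) ** 2


def test_extract_patch_center_and_corner(rng):
    img = rng.integers(0, 256, (200, 200, 3), dtype=np.uint8)
    p = extract_patch(img, (100, 100))
    assert p.shape == (40, 40, 3)
    assert np.array_equal(p, img[80:120, 80:120])
    corner = extract_patch(img, (0, 0))
    assert corner.shape == (40, 40, 3)
    # three quadrants are edge replication of the (0,0) pixel's row/col
    assert (corner[:20, :20] == img[0, 0]).all()
    with pytest.raises(ValueError):
        extract_patch(img, (200, 100))


def test_constant_patch_has_no_keypoints():
    assert detect_keypoints(np.full((40, 40), 0.5)).shape == (0, 2)


def test_square_corners_detected_and_match_oracle():
    patch = np.zeros((40, 40))
    patch[12:28, 12:28] = 1.0
    kps = {tuple(k) for k in detect_keypoints(patch)}
    expected = {(12, 12), (12, 27), (27, 12), (27, 27)}
    # every true corner found within 1 px
    for ex, ey in expected:
        assert any(abs(x - ex) <= 1 and abs(y - ey) <= 1 for x, y in kps)
    resp = harris_response_oracle(patch)
    for x, y in kps:
        assert resp[y, x] > 0.01 * resp.max()


def test_keypoints_shift_with_translation(rng):
    patch = np.zeros((40, 40))
    patch[10:20, 10:20] = rng.random((10, 10))
    base = {tuple(k) for k in detect_keypoints(patch)}
    shifted_patch = np.roll(patch, (4, 5), axis=(0, 1))
    shifted = {tuple(k) for k in detect_keypoints(shifted_patch)}
    interior = {(x + 5, y + 4) for x, y in base if 5 <= x < 30 and 5 <= y < 30}
    assert interior <= shifted


def test_descriptors_shape_and_determinism(rng):
    patch = rng.random((40, 40))
    kps = detect_keypoints(patch)
    assert len(kps) > 0
    d1 = describe(patch, kps)
    d2 = describe(patch, kps)
    assert d1.shape == (len(kps), DESCRIPTOR_DIM)
    assert np.isfinite(d1).all()
    assert (np.linalg.norm(d1, axis=1) <= 1.0 + 1e-9).all()
    assert np.array_equal(d1, d2)
    assert describe(patch, np.empty((0, 2))).shape == (0, DESCRIPTOR_DIM)


def test_vocabulary_recovers_separated_blobs(rng):
    centers = rng.random((10, DESCRIPTOR_DIM)) * 10
    descs = np.vstack([c + rng.normal(0, 0.01, (30, DESCRIPTOR_DIM)) for c in centers])
    vocab = build_vocabulary(descs, k=10, seed=0)
    # one centroid per blob: nearest-centroid assignment respects blob identity
    d2 = ((descs[:, None, :] - vocab.centroids[None]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    blobs = np.repeat(np.arange(10), 30)
    for b in range(10):
        assert np.unique(assign[blobs == b]).size == 1
    assert np.unique(assign).size == 10


def test_vocabulary_exactly_k_descriptors(rng):
    descs = rng.random((10, DESCRIPTOR_DIM))
    vocab = build_vocabulary(descs, k=10, seed=1)
    got = {tuple(np.round(c, 9)) for c in vocab.centroids}
    want = {tuple(np.round(d, 9)) for d in descs}
    assert got == want
    with pytest.raises(ValueError):
        build_vocabulary(descs[:5], k=10)


def test_vocabulary_deterministic(rng):
    descs = rng.random((200, DESCRIPTOR_DIM))
    v1 = build_vocabulary(descs, k=10, seed=3)
    v2 = build_vocabulary(descs, k=10, seed=3)
    assert np.array_equal(v1.centroids, v2.centroids)


def test_encode_one_hot_and_empty(rng):
    descs = rng.random((12, DESCRIPTOR_DIM))
    vocab = build_vocabulary(descs, k=10, seed=0)
    hist, empty = encode(vocab.centroids[3][None, :], vocab)
    assert not empty
    assert hist[3] == 1.0 and hist.sum() == 1.0
    hist, empty = encode(np.empty((0, DESCRIPTOR_DIM)), vocab)
    assert empty and (hist == 0).all()


def test_encode_matches_exhaustive_nearest_centroid(rng):
    vocab = build_vocabulary(rng.random((50, DESCRIPTOR_DIM)), k=10, seed=0)
    for _ in range(20):
        descs = rng.random((rng.integers(1, 60), DESCRIPTOR_DIM))
        hist, empty = encode(descs, vocab)
        counts = np.zeros(10)
        for d in descs:  # exhaustive scan
            best, best_d = 0, np.inf
            for j, c in enumerate(vocab.centroids):
                dist = ((d - c) ** 2).sum()
                if dist < best_d:
                    best, best_d = j, dist
            counts[best] += 1
        assert not empty
        assert np.allclose(hist, counts / counts.sum())


def test_classifier_separable_and_deterministic(rng):
    n = 60
    node_h = np.hstack([rng.dirichlet(np.ones(5), n), np.zeros((n, 5))])
    non_h = np.hstack([np.zeros((n, 5)), rng.dirichlet(np.ones(5), n)])
    X = np.vstack([node_h, non_h])
    y = np.array([NODE] * n + [NON_NODE] * n)
    clf = train_patch_classifier(X, y, n_trees=100, seed=0)
    assert (clf.predict(X) == y).all()
    clf2 = train_patch_classifier(X, y, n_trees=100, seed=0)
    assert (clf2.predict(X) == clf.predict(X)).all()


def test_label_shuffle_gives_chance_oob(rng):
    X = rng.dirichlet(np.ones(10), 300)
    y = np.array([NODE, NON_NODE] * 150)
    rng.shuffle(y)
    clf = train_patch_classifier(X, y, n_trees=200, seed=0)
    assert abs(clf.oob_score - 0.5) <= 0.15


def test_single_class_training_rejected(rng):
    X = rng.dirichlet(np.ones(10), 20)
    with pytest.raises(ValueError):
        train_patch_classifier(X, [NODE] * 20)


def test_constant_patch_candidate_is_non_node(rng):
    vocab = build_vocabulary(rng.random((20, DESCRIPTOR_DIM)), k=10, seed=0)
    X = np.vstack([rng.dirichlet(np.ones(10), 10), np.zeros((10, 10))])
    y = np.array([NODE] * 10 + [NON_NODE] * 10)
    clf = train_patch_classifier(X, y, n_trees=50, seed=0)
    img = np.full((100, 100, 3), 120, dtype=np.uint8)
    cand = Candidate(x=50, y=50)
    assert classify_candidate(img, cand, vocab, clf) == NON_NODE
    assert cand.status == "removed_bovw"
    assert "no keypoints" in cand.reason


def test_accepted_candidate_keeps_its_pixel(small_sequence, small_models):
    _, frames, gt = small_sequence
    models, _ = small_models
    x, y, _ = gt.frames[-1].nodes[0]
    cand = Candidate(x=int(round(x)), y=int(round(y)))
    label = classify_candidate(frames[-1], cand, models.vocab, models.classifier)
    assert label == NODE
    assert cand.status == "accepted"
    assert (cand.x, cand.y) == (int(round(x)), int(round(y)))
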