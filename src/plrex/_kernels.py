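"""Numba kernels for the performance-critical inner loops.

Everything in this module operates on plain numpy arrays: 2-bit base codes
(uint8, A=0 C=1 G=2 T=3), flat read storage (codes + offsets), and the
CSR-layout minhash tables (sorted key array, per-key start offsets, flat id
list).  The Python modules wrap these kernels in the documented API; the
whole-pair driver `run_pair_kernel` chains them so that a complete extension
of one read pair costs a single Python call.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# uint64 constants (numba-safe)
_U0 = np.uint64(0)
_U1 = np.uint64(1)
_U2 = np.uint64(2)
_U3 = np.uint64(3)
_U6 = np.uint64(6)
_U33 = np.uint64(33)
_UMAX = np.uint64(0xFFFFFFFFFFFFFFFF)
_M1 = np.uint64(0xFF51AFD7ED558CCD)
_M2 = np.uint64(0xC4CEB9FE1A85EC53)

# task status codes
ST_ACTIVE = 0
ST_MATE_FOUND = 1
ST_FAILED = 2
ST_STOPPED = 3


@njit(cache=True)
def _fmix64(z):
    # murmur3 64-bit finalizer; a bijective integer mixer
    z ^= z >> _U33
    z *= _M1
    z ^= z >> _U33
    z *= _M2
    z ^= z >> _U33
    return z


@njit(cache=True)
def hamming_kernel(a, b):
    mm = 0
    for i in range(a.shape[0]):
        if a[i] != b[i]:
            mm += 1
    return mm


@njit(cache=True)
def _rc_into(src, dst):
    n = src.shape[0]
    for i in range(n):
        dst[i] = 3 - src[n - 1 - i]


@njit(cache=True)
def rc_store_kernel(codes, offsets):
    """Per-read reverse complement of flat read storage, same offsets."""
    out = np.empty_like(codes)
    for i in range(offsets.shape[0] - 1):
        s = offsets[i]
        e = offsets[i + 1]
        _rc_into(codes[s:e], out[s:e])
    return out


@njit(cache=True)
def signature_into(codes, start, end, k, seeds, out):
    """Minhash signature of codes[start:end] over canonical k-mers.

    out[x] receives the minimum of hash function x over all k-mers; returns
    False (and leaves out at UMAX) when the sequence is shorter than k.
    """
    h = seeds.shape[0]
    for x in range(h):
        out[x] = _UMAX
    n = end - start
    if n < k:
        return False
    if k >= 32:
        mask = _UMAX
    else:
        mask = (_U1 << np.uint64(2 * k)) - _U1
    shift_rc = np.uint64(2 * (k - 1))
    fwd = _U0
    rc = _U0
    for i in range(n):
        c = np.uint64(codes[start + i])
        fwd = ((fwd << _U2) | c) & mask
        rc = (rc >> _U2) | ((_U3 - c) << shift_rc)
        if i >= k - 1:
            canon = fwd if fwd < rc else rc
            for x in range(h):
                v = _fmix64(canon ^ seeds[x])
                if v < out[x]:
                    out[x] = v
    return True


@njit(cache=True)
def signature_keys(codes, offsets, k, seeds):
    """Per-read table keys for index construction.

    Key for read i in table x is (signature[x] << 6) | x, so one sorted key
    array can hold all h tables.  Reads shorter than k are flagged invalid.
    """
    n_reads = offsets.shape[0] - 1
    h = seeds.shape[0]
    keys = np.empty(n_reads * h, np.uint64)
    rids = np.empty(n_reads * h, np.int32)
    valid = np.zeros(n_reads, np.bool_)
    sig = np.empty(h, np.uint64)
    for i in range(n_reads):
        ok = signature_into(codes, offsets[i], offsets[i + 1], k, seeds, sig)
        valid[i] = ok
        base = i * h
        for x in range(h):
            rids[base + x] = i
            keys[base + x] = (sig[x] << _U6) | np.uint64(x)
    return keys, rids, valid


@njit(cache=True)
def query_ids(sig, keys_sorted, key_starts, ids_flat, cap):
    """Union of id lists under the signature's h keys, deduplicated, sorted.

    Per-key lists are truncated at `cap` ids to bound repeat blow-up.
    """
    h = sig.shape[0]
    n_keys = keys_sorted.shape[0]
    locs = np.empty(h, np.int64)
    total = 0
    for x in range(h):
        key = (sig[x] << _U6) | np.uint64(x)
        pos = np.searchsorted(keys_sorted, key)
        if pos < n_keys and keys_sorted[pos] == key:
            locs[x] = pos
            cnt = key_starts[pos + 1] - key_starts[pos]
            if cnt > cap:
                cnt = cap
            total += cnt
        else:
            locs[x] = -1
    out = np.empty(total, np.int32)
    t = 0
    for x in range(h):
        p = locs[x]
        if p >= 0:
            s = key_starts[p]
            e = key_starts[p + 1]
            if e - s > cap:
                e = s + cap
            for j in range(s, e):
                out[t] = ids_flat[j]
                t += 1
    out = np.sort(out)
    u = 0
    for i in range(out.shape[0]):
        if i == 0 or out[i] != out[i - 1]:
            out[u] = out[i]
            u += 1
    return out[:u]


@njit(cache=True)
def best_alignment_kernel(anchor, cand_f, cand_r, max_mm, min_frac):
    """Best admissible indel-free placement of a candidate on the anchor.

    Evaluates every shift in [0, |anchor|) for both orientations.  Admissible
    placements overlap by at least min_frac * |candidate| bases and mismatch
    in at most max_mm positions.  Ties break by fewer mismatches, larger
    overlap, smaller shift, forward orientation.  Returns
    (mismatches, overlap, shift, orientation); mismatches == -1 means none.
    """
    la = anchor.shape[0]
    lc = cand_f.shape[0]
    best_mm = -1
    best_ov = 0
    best_sh = 0
    best_or = 0
    min_ov = min_frac * lc
    for orient in range(2):
        cand = cand_f if orient == 0 else cand_r
        for shift in range(la):
            ov = la - shift
            if lc < ov:
                ov = lc
            if ov < min_ov or ov < 1:
                break  # overlap only shrinks with larger shift
            if best_mm == 0 and (ov < best_ov or (ov == best_ov and shift >= best_sh)):
                # a perfect placement is held; remaining shifts have
                # non-increasing overlap and can no longer win the
                # (mismatches, overlap, shift, orientation) tie-break
                break
            # branch-free probe over the first bases (vectorizable), then a
            # full branch-free count only for the placements that survive
            lim = 16 if ov >= 16 else ov
            mm = 0
            for t in range(lim):
                mm += anchor[shift + t] != cand[t]
            if mm > max_mm:
                continue
            for t in range(lim, ov):
                mm += anchor[shift + t] != cand[t]
            if mm > max_mm:
                continue
            if best_mm < 0 or mm < best_mm or (
                mm == best_mm and (ov > best_ov or (ov == best_ov and shift < best_sh))
            ):
                best_mm = mm
                best_ov = ov
                best_sh = shift
                best_or = orient
    return best_mm, best_ov, best_sh, best_or


@njit(cache=True)
def align_batch(anchor, cand_ids, read_codes, read_rc_codes, read_offsets,
                max_mm, min_frac, exclude_a, exclude_b):
    """Align every retrieved candidate to the anchor window.

    `read_rc_codes` holds the precomputed reverse complement of every read
    at the same offsets as `read_codes`.  Candidates with no admissible
    placement, and the excluded (own-pair) read ids, are dropped.  Input
    ids must be sorted; output preserves order.
    """
    n = cand_ids.shape[0]
    ids = np.empty(n, np.int32)
    shifts = np.empty(n, np.int32)
    orients = np.empty(n, np.int8)
    mms = np.empty(n, np.int32)
    ovs = np.empty(n, np.int32)
    cnt = 0
    for ii in range(n):
        rid = cand_ids[ii]
        if rid == exclude_a or rid == exclude_b:
            continue
        s = read_offsets[rid]
        e = read_offsets[rid + 1]
        mm, ov, sh, orient = best_alignment_kernel(
            anchor, read_codes[s:e], read_rc_codes[s:e], max_mm, min_frac)
        if mm >= 0:
            ids[cnt] = rid
            shifts[cnt] = sh
            orients[cnt] = orient
            mms[cnt] = mm
            ovs[cnt] = ov
            cnt += 1
    return ids[:cnt], shifts[:cnt], orients[:cnt], mms[:cnt], ovs[:cnt]


@njit(cache=True)
def filter_batch(ids, rel_ov, partner_ids, partner_active):
    """Paired/unpaired candidate filter.

    A candidate whose mate (id ^ 1; reads of pair p are 2p and 2p+1) occurs
    in the partner task's batch is kept unconditionally.  Over the remaining
    unpaired candidates T = max(floor(O_i * 10) / 10) is computed from the
    relative overlaps O_i and entries with O_i < T are dropped.  With an
    inactive partner every candidate is treated as unpaired.
    """
    n = ids.shape[0]
    keep = np.zeros(n, np.bool_)
    rescued = np.zeros(n, np.bool_)
    np_ids = partner_ids.shape[0]
    if partner_active:
        for i in range(n):
            mate = ids[i] ^ 1
            pos = np.searchsorted(partner_ids, mate)
            if pos < np_ids and partner_ids[pos] == mate:
                rescued[i] = True
    thr = -1.0
    for i in range(n):
        if not rescued[i]:
            b = np.floor(rel_ov[i] * 10.0) / 10.0
            if b > thr:
                thr = b
    for i in range(n):
        if rescued[i]:
            keep[i] = True
        elif rel_ov[i] >= thr:
            keep[i] = True
    return keep, rescued


@njit(cache=True)
def msa_counts_kernel(anchor, mem_flat, mem_offs, shifts, alive, ncols):
    counts = np.zeros((4, ncols), np.int32)
    for col in range(anchor.shape[0]):
        counts[anchor[col], col] += 1
    for mi in range(shifts.shape[0]):
        if alive[mi]:
            s = mem_offs[mi]
            e = mem_offs[mi + 1]
            sh = shifts[mi]
            for t in range(e - s):
                counts[mem_flat[s + t], sh + t] += 1
    return counts


@njit(cache=True)
def _remove_member(counts, mem_flat, mem_offs, shifts, mi):
    s = mem_offs[mi]
    e = mem_offs[mi + 1]
    sh = shifts[mi]
    for t in range(e - s):
        counts[mem_flat[s + t], sh + t] -= 1


@njit(cache=True)
def refine_kernel(anchor, mem_flat, mem_offs, shifts, alive, counts, frac, passes):
    """Column-content refinement over anchor-covered columns.

    For each column, a non-consensus base x reaching frac * coverage triggers
    a removal: members disagreeing with the anchor's x, or members carrying a
    foreign x.  Counts are updated immediately, so later columns see the
    refined MSA.  Only members covering the column are candidates for
    removal.  Returns the number of removed members.
    """
    la = anchor.shape[0]
    nm = shifts.shape[0]
    removed_total = 0
    for _ in range(passes):
        removed_pass = 0
        for col in range(la):
            guard = 0
            while guard <= nm:
                guard += 1
                cov = counts[0, col] + counts[1, col] + counts[2, col] + counts[3, col]
                if cov <= 0:
                    break
                cons = 0
                bc = counts[0, col]
                for b in range(1, 4):
                    if counts[b, col] > bc:
                        bc = counts[b, col]
                        cons = b
                removed_here = 0
                trigger = -1
                for x in range(4):
                    if x == cons:
                        continue
                    cx = counts[x, col]
                    if cx > 0 and cx >= frac * cov:
                        trigger = x
                        break
                if trigger < 0:
                    break
                x = trigger
                if anchor[col] == x:
                    for mi in range(nm):
                        if alive[mi]:
                            sh = shifts[mi]
                            ln = mem_offs[mi + 1] - mem_offs[mi]
                            if sh <= col < sh + ln:
                                if mem_flat[mem_offs[mi] + col - sh] != x:
                                    _remove_member(counts, mem_flat, mem_offs, shifts, mi)
                                    alive[mi] = False
                                    removed_here += 1
                else:
                    for mi in range(nm):
                        if alive[mi]:
                            sh = shifts[mi]
                            ln = mem_offs[mi + 1] - mem_offs[mi]
                            if sh <= col < sh + ln:
                                if mem_flat[mem_offs[mi] + col - sh] == x:
                                    _remove_member(counts, mem_flat, mem_offs, shifts, mi)
                                    alive[mi] = False
                                    removed_here += 1
                if removed_here == 0:
                    break
                removed_pass += removed_here
        removed_total += removed_pass
        if removed_pass == 0:
            break
    return removed_total


@njit(cache=True)
def consensus_kernel(counts):
    ncols = counts.shape[1]
    out = np.empty(ncols, np.uint8)
    for col in range(ncols):
        cons = 0
        bc = counts[0, col]
        for b in range(1, 4):
            if counts[b, col] > bc:
                bc = counts[b, col]
                cons = b
        out[col] = cons
    return out


@njit(cache=True)
def extend_scan(counts, anchor_len, stepsize, min_cov):
    """Find j: the last column of the appendable consensus run.

    Columns i = anchor_len .. j must exist, be contiguous, each reach
    coverage >= min_cov, and satisfy j - i <= stepsize - 1 (so at most
    stepsize bases are appended).  Returns -1 when column i is missing or
    under-covered.
    """
    ncols = counts.shape[1]
    i = anchor_len
    if i >= ncols:
        return -1
    cov = counts[0, i] + counts[1, i] + counts[2, i] + counts[3, i]
    if cov < min_cov:
        return -1
    j = i
    while j + 1 < ncols and (j + 1 - i) <= stepsize - 1:
        cov = counts[0, j + 1] + counts[1, j + 1] + counts[2, j + 1] + counts[3, j + 1]
        if cov < min_cov:
            break
        j += 1
    return j


@njit(cache=True)
def mate_scan(contig, clen, mate, start_p, min_len, max_len, max_mm):
    """Scan mate placements p ascending; first admissible placement wins.

    Admissible: min_len <= p + |mate| <= max_len, fully contained in the
    contig, hamming <= max_mm.  Returns (position or -1, next start so that
    earlier placements are never revisited).
    """
    lm = mate.shape[0]
    lo = min_len - lm
    if lo < 0:
        lo = 0
    p = start_p
    if p < lo:
        p = lo
    hi = clen - lm
    hi2 = max_len - lm
    if hi2 < hi:
        hi = hi2
    while p <= hi:
        mm = 0
        ok = True
        for t in range(lm):
            if contig[p + t] != mate[t]:
                mm += 1
                if mm > max_mm:
                    ok = False
                    break
        if ok:
            return p, p
        p += 1
    nxt = hi + 1
    if nxt < start_p:
        nxt = start_p
    return -1, nxt


@njit(cache=True)
def best_merge_overlap(a, b, min_ov, max_mm_frac, min_len, max_len):
    """Longest admissible overlap of a suffix of `a` with a prefix of `b`.

    Admissible: overlap >= min_ov, mismatch fraction <= max_mm_frac, merged
    length la + lb - overlap within [min_len, max_len].  Returns -1 if none.
    """
    la = a.shape[0]
    lb = b.shape[0]
    max_ov = la if la < lb else lb
    for ov in range(max_ov, min_ov - 1, -1):
        merged = la + lb - ov
        if merged < min_len or merged > max_len:
            continue
        allowed = int(max_mm_frac * ov)
        mm = 0
        ok = True
        for t in range(ov):
            if a[la - ov + t] != b[t]:
                mm += 1
                if mm > allowed:
                    ok = False
                    break
        if ok:
            return ov
    return -1


@njit(cache=True)
def count_placements(genome, read, lo, hi, max_mm):
    """Number of positions p in [lo, hi] with hamming(genome[p:p+L], read) <= max_mm."""
    l = read.shape[0]
    if lo < 0:
        lo = 0
    if hi > genome.shape[0] - l:
        hi = genome.shape[0] - l
    n = 0
    for p in range(lo, hi + 1):
        mm = 0
        ok = True
        for t in range(l):
            if genome[p + t] != read[t]:
                mm += 1
                if mm > max_mm:
                    ok = False
                    break
        if ok:
            n += 1
    return n


@njit(cache=True)
def run_pair_kernel(id1, id2,
                    read_codes, read_rc_codes, read_offsets,
                    keys_sorted, key_starts, ids_flat, cap,
                    k, seeds,
                    max_mm, min_frac,
                    stepsize, min_cov, refine_frac, refine_passes,
                    min_len, max_len, mate_mm_frac, run_aux):
    """Run the four extension tasks of one read pair to completion.

    Task layout: 0 = primary from read 1 (target RC2), 1 = auxiliary from
    RC2, 2 = primary from read 2 (target RC1), 3 = auxiliary from RC1.
    Partner pairs are (0,1) and (2,3); tasks advance in lockstep so the
    paired-candidate rescue sees same-iteration partner batches.

    With run_aux == 0 the auxiliary tasks are not processed (they report
    `stopped` with their bare starting sequence).  The caller may only
    request this when the auxiliary outputs are provably unused: outward
    extension disabled and all reads of equal length, in which case every
    candidate has the same relative overlap, the decile threshold keeps all
    of them, and the paired rescue cannot change any keep decision.

    Returns (status[4], contigs buffer, contig lengths, mate positions).
    """
    h = seeds.shape[0]
    l1 = read_offsets[id1 + 1] - read_offsets[id1]
    l2 = read_offsets[id2 + 1] - read_offsets[id2]
    s1 = read_codes[read_offsets[id1]:read_offsets[id1 + 1]]
    s2 = read_codes[read_offsets[id2]:read_offsets[id2 + 1]]
    rc1 = np.empty(l1, np.uint8)
    rc2 = np.empty(l2, np.uint8)
    _rc_into(s1, rc1)
    _rc_into(s2, rc2)

    buf_len = max_len + stepsize + 1
    contigs = np.zeros((4, buf_len), np.uint8)
    contigs[0, :l1] = s1
    contigs[1, :l2] = rc2
    contigs[2, :l2] = s2
    contigs[3, :l1] = rc1
    clen = np.empty(4, np.int64)
    clen[0] = l1
    clen[1] = l2
    clen[2] = l2
    clen[3] = l1
    wlen = np.empty(4, np.int64)
    wlen[0] = l1
    wlen[1] = l2
    wlen[2] = l2
    wlen[3] = l1

    status = np.zeros(4, np.int8)
    if run_aux == 0:
        status[1] = ST_STOPPED
        status[3] = ST_STOPPED
    mate_pos = np.full(4, -1, np.int64)
    next_p = np.zeros(4, np.int64)
    next_p[0] = min_len - l2 if min_len - l2 > 0 else 0
    next_p[2] = min_len - l1 if min_len - l1 > 0 else 0
    mate_mm0 = int(np.ceil(mate_mm_frac * l2))
    mate_mm2 = int(np.ceil(mate_mm_frac * l1))

    if l1 < k or l2 < k:
        for t in range(4):
            status[t] = ST_FAILED
        return status, contigs, clen, mate_pos

    sig = np.empty(h, np.uint64)
    empty_i32 = np.empty(0, np.int32)
    empty_i8 = np.empty(0, np.int8)
    empty_f64 = np.empty(0, np.float64)

    for _it in range(max_len + 1):
        if (status[0] != ST_ACTIVE and status[1] != ST_ACTIVE
                and status[2] != ST_ACTIVE and status[3] != ST_ACTIVE):
            break

        # phase 1: gather + align candidate batches for every active task
        b_ids = [empty_i32, empty_i32, empty_i32, empty_i32]
        b_shift = [empty_i32, empty_i32, empty_i32, empty_i32]
        b_orient = [empty_i8, empty_i8, empty_i8, empty_i8]
        b_relov = [empty_f64, empty_f64, empty_f64, empty_f64]
        for t in range(4):
            if status[t] != ST_ACTIVE:
                continue
            ws = clen[t] - wlen[t]
            window = contigs[t, ws:clen[t]]
            signature_into(window, 0, window.shape[0], k, seeds, sig)
            cand = query_ids(sig, keys_sorted, key_starts, ids_flat, cap)
            ids, shifts, orients, mms, ovs = align_batch(
                window, cand, read_codes, read_rc_codes, read_offsets,
                max_mm, min_frac, id1, id2)
            relov = np.empty(ids.shape[0], np.float64)
            for i in range(ids.shape[0]):
                rid = ids[i]
                relov[i] = (read_offsets[rid + 1] - read_offsets[rid]) / wlen[t]
            b_ids[t] = ids
            b_shift[t] = shifts
            b_orient[t] = orients
            b_relov[t] = relov

        # phase 2: filter with partner exchange, then MSA + extension
        for t in range(4):
            if status[t] != ST_ACTIVE:
                continue
            partner = t ^ 1
            partner_active = status[partner] == ST_ACTIVE
            window = contigs[t, clen[t] - wlen[t]:clen[t]]
            keep, _resc = filter_batch(b_ids[t], b_relov[t],
                                       b_ids[partner], partner_active)
            nk = 0
            for i in range(keep.shape[0]):
                if keep[i]:
                    nk += 1
            mem_offs = np.empty(nk + 1, np.int64)
            mem_shifts = np.empty(nk, np.int64)
            mem_offs[0] = 0
            mi = 0
            total = 0
            for i in range(keep.shape[0]):
                if keep[i]:
                    rid = b_ids[t][i]
                    ln = read_offsets[rid + 1] - read_offsets[rid]
                    total += ln
                    mem_offs[mi + 1] = total
                    mem_shifts[mi] = b_shift[t][i]
                    mi += 1
            mem_flat = np.empty(total, np.uint8)
            mi = 0
            for i in range(keep.shape[0]):
                if keep[i]:
                    rid = b_ids[t][i]
                    s = read_offsets[rid]
                    e = read_offsets[rid + 1]
                    dst = mem_flat[mem_offs[mi]:mem_offs[mi + 1]]
                    if b_orient[t][i] == 0:
                        for j in range(e - s):
                            dst[j] = read_codes[s + j]
                    else:
                        for j in range(e - s):
                            dst[j] = read_rc_codes[s + j]
                    mi += 1
            ncols = wlen[t]
            for i in range(nk):
                end_col = mem_shifts[i] + mem_offs[i + 1] - mem_offs[i]
                if end_col > ncols:
                    ncols = end_col
            alive = np.ones(nk, np.bool_)
            counts = msa_counts_kernel(window, mem_flat, mem_offs, mem_shifts,
                                       alive, ncols)
            refine_kernel(window, mem_flat, mem_offs, mem_shifts, alive,
                          counts, refine_frac, refine_passes)
            j = extend_scan(counts, wlen[t], stepsize, min_cov)
            if j < 0:
                status[t] = ST_FAILED
                continue
            cons = consensus_kernel(counts)
            n_app = j + 1 - wlen[t]
            for u in range(n_app):
                contigs[t, clen[t] + u] = cons[wlen[t] + u]
            clen[t] += n_app

            # primary tasks: look for the mate over newly admissible placements
            if t == 0 or t == 2:
                mate = rc2 if t == 0 else rc1
                mmx = mate_mm0 if t == 0 else mate_mm2
                pos, nxt = mate_scan(contigs[t], clen[t], mate, next_p[t],
                                     min_len, max_len, mmx)
                next_p[t] = nxt
                if pos >= 0:
                    mate_pos[t] = pos
                    clen[t] = pos + mate.shape[0]
                    for u in range(mate.shape[0]):
                        contigs[t, pos + u] = mate[u]
                    status[t] = ST_MATE_FOUND
                    continue
            if clen[t] >= max_len:
                status[t] = ST_FAILED if (t == 0 or t == 2) else ST_STOPPED

        # auxiliary tasks stop as soon as their primary partner stops
        if status[0] != ST_ACTIVE and status[1] == ST_ACTIVE:
            status[1] = ST_STOPPED
        if status[2] != ST_ACTIVE and status[3] == ST_ACTIVE:
            status[3] = ST_STOPPED

    return status, contigs, clen, mate_pos
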