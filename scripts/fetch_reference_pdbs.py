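#!/usr/bin/env python
"""Download the two crystal reference structures (3H4J, 3DAE) into data/.

Needs network access to files.rcsb.org.  Once fetched, the reference
worked-example acceptance test and targets t1/t2 run offline from data/.
"""

import os
import sys
import urllib.request

REPO = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
URL = "https://files.rcsb.org/download/{}.pdb"


def main() -> int:
    outdir = os.path.join(REPO, "data")
    os.makedirs(outdir, exist_ok=True)
    for code in ("3H4J", "3DAE"):
        dest = os.path.join(outdir, f"{code}.pdb")
        if os.path.exists(dest):
            print(f"{dest} already present")
            continue
        print(f"fetching {code} ...")
        with urllib.request.urlopen(URL.format(code), timeout=60) as resp:
            text = resp.read().decode()
        with open(dest, "w") as fh:
            fh.write(text)
        print(f"wrote {dest} ({len(text)} bytes)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
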