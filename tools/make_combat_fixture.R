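# One-time companion to make_combat_fixture.py: runs the Bioconductor reference
# ComBat (sva) on tests/fixtures/combat_input.tsv and freezes the harmonized
# output as combat_sva_expected.tsv (subjects x features, same column order).
suppressMessages(library(sva))

args <- commandArgs(trailingOnly = FALSE)
script_dir <- dirname(sub("--file=", "", args[grep("--file=", args)]))
fix <- file.path(script_dir, "..", "tests", "fixtures")

inp <- read.delim(file.path(fix, "combat_input.tsv"), check.names = FALSE)
feat <- as.matrix(inp[, grep("^f", names(inp))])
mod <- model.matrix(~ group + age, data = inp)
out <- ComBat(dat = t(feat), batch = inp$site, mod = mod, par.prior = TRUE)
write.table(
  format(t(out), digits = 10, scientific = FALSE, trim = TRUE),
  file.path(fix, "combat_sva_expected.tsv"),
  sep = "\t", quote = FALSE, row.names = FALSE
)
cat("wrote", file.path(fix, "combat_sva_expected.tsv"), "\n")
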